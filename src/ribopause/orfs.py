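"""Transcript and ORF records in transcript space.

All coordinates are 0-based, half-open, in nucleotides on the mature
transcript (no genome/splicing awareness).  A record carries the full
transcript sequence plus the CDS interval; codon index ``k`` covers
nucleotides ``[cds_start + 3k, cds_start + 3k + 3)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ORF_TABLE_COLUMNS = ("transcript_id", "cds_start", "cds_length_nt")


@dataclass(frozen=True)
class OrfRecord:
    """One transcript with an annotated coding sequence.

    Parameters
    ----------
    transcript_id : str
        Unique transcript name.
    sequence : str
        Full transcript sequence over {A, C, G, T}; U is accepted on
        input and normalized to T.
    cds_start : int
        0-based nt offset of the first CDS nucleotide.
    cds_length : int
        CDS length in nt, a multiple of 3.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_length: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: cds_length {self.cds_length} is not a multiple of 3"
            )
        if self.cds_start < 0 or self.cds_start + self.cds_length > len(seq):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, "
                f"{self.cds_start + self.cds_length}) outside transcript of length {len(seq)}"
            )
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.transcript_id}: invalid characters {sorted(bad)}")

    @property
    def codon_count(self) -> int:
        return self.cds_length // 3

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_start + self.cds_length]

    def codons(self) -> list[str]:
        cds = self.cds
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]

    def translation(self) -> str:
        """Amino-acid sequence of the CDS (stops rendered as ``*``)."""
        return str(Seq(self.cds).translate())

    def is_translatable(self) -> bool:
        """True when no internal stop codon precedes the last codon."""
        return "*" not in self.translation()[:-1]


def write_transcriptome_fasta(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(o.sequence), id=o.transcript_id, description="")
        for o in orfs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_orf_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ORF_TABLE_COLUMNS)
        for o in orfs:
            writer.writerow([o.transcript_id, o.cds_start, o.cds_length])


def read_orfs(fasta_path: str | Path, table_path: str | Path) -> list[OrfRecord]:
    """Load a transcriptome FASTA plus its ORF annotation table.

    Every table row must have a FASTA sequence; FASTA records absent from
    the table are ignored (e.g. non-coding contaminant references).
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    orfs: list[OrfRecord] = []
    with open(table_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            tid = row["transcript_id"]
            if tid not in seqs:
                raise ValueError(f"ORF table names {tid!r} but the FASTA lacks it")
            orfs.append(
                OrfRecord(
                    transcript_id=tid,
                    sequence=seqs[tid],
                    cds_start=int(row["cds_start"]),
                    cds_length=int(row["cds_length_nt"]),
                )
            )
    return orfs


def orf_index(orfs: Iterable[OrfRecord]) -> dict[str, OrfRecord]:
    index: dict[str, OrfRecord] = {}
    for o in orfs:
        if o.transcript_id in index:
            raise ValueError(f"duplicate transcript_id {o.transcript_id!r}")
        index[o.transcript_id] = o
    return index
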