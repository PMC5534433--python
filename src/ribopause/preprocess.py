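"""Raw-read preprocessing: linker trimming, UMI extraction, deduplication.

The library layout puts the footprint insert first, followed by the
random barcode (UMI), the fixed multiplex barcode and the constant
linker.  Trimming finds the leftmost prefix-match of the expected
barcode+linker tail (reads shorter than the full tail match on a
configurable minimum overlap), strips it, and recovers the UMI from the
bases immediately upstream.

Deduplication collapses PCR duplicates on the (transcript, 5' position,
length, UMI) key, keeping the first occurrence; the key includes length
because nested reads at the same 5' end carry distinct conformational
information.  Length restriction keeps only the two analyzed classes,
20-22 nt (short) and 27-29 nt (long).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .asite import SUPPORTED_LENGTHS, length_class
from .orfs import OrfRecord

DEDUP_KEY = ["transcript_id", "pos5", "length", "umi"]
FOOTPRINT_COLUMNS = ["transcript_id", "pos5", "length", "umi"]


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    insert: str
    umi: str


@dataclass
class TrimResult:
    kept: list[TrimmedRead]
    rejected: list[tuple[str, str]]  # (read_id, reason)
    counts: dict[str, int] = field(default_factory=dict)


def _find_linker(seq: str, linker: str, min_overlap: int) -> int:
    """Leftmost start of a prefix-match of `linker` in `seq`, or -1.

    A match at position i uses overlap min(len(linker), len(seq)-i) and
    requires that overlap to be at least `min_overlap`.
    """
    n, m = len(seq), len(linker)
    full = seq.find(linker)
    limit = full if full != -1 else n - min_overlap
    for i in range(0, limit + 1):
        ov = min(m, n - i)
        if ov < min_overlap:
            break
        if seq[i : i + ov] == linker[:ov]:
            return i
    return full


def parse_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence); truncated records abort with file context."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc


def extract_umi_and_trim(
    fastq_path: str | Path,
    linker_sequence: str,
    umi_length: int = 7,
    min_overlap: int = 6,
) -> TrimResult:
    """Strip the linker tail and recover insert + UMI from each raw read.

    ``linker_sequence`` is everything expected after the UMI, i.e. the
    multiplex barcode plus the constant linker.  Reads with no
    recognizable linker (``no_linker``) or with too few bases before it
    to hold a UMI and a non-empty insert (``no_insert``) go to the
    reject stream with a reason.
    """
    if not linker_sequence:
        raise ValueError("linker_sequence must be non-empty")
    kept: list[TrimmedRead] = []
    rejected: list[tuple[str, str]] = []
    for read_id, seq in parse_fastq(fastq_path):
        i = _find_linker(seq, linker_sequence, min_overlap)
        if i < 0:
            rejected.append((read_id, "no_linker"))
        elif i <= umi_length:
            rejected.append((read_id, "no_insert"))
        else:
            kept.append(TrimmedRead(read_id, seq[: i - umi_length], seq[i - umi_length : i]))
    counts = {"input": len(kept) + len(rejected), "kept": len(kept), "rejected": len(rejected)}
    return TrimResult(kept=kept, rejected=rejected, counts=counts)


class ExactMatchMapper:
    """Unique exact-match alignment of inserts to a transcriptome.

    Test plumbing only: full-length perfect matches, multi-hit reads
    discarded and counted.  Real libraries are aligned with a standard
    read mapper; this pipeline consumes those alignments.
    """

    def __init__(self, orfs: Sequence[OrfRecord]):
        self._seqs = [(o.transcript_id, o.sequence) for o in orfs]

    def map_insert(self, insert: str) -> list[tuple[str, int]]:
        hits: list[tuple[str, int]] = []
        for tid, seq in self._seqs:
            start = seq.find(insert)
            while start != -1:
                hits.append((tid, start))
                start = seq.find(insert, start + 1)
        return hits

    def map_reads(self, reads: Iterable[TrimmedRead]) -> tuple[pd.DataFrame, dict[str, int]]:
        rows = []
        counts = {"mapped": 0, "unmapped": 0, "multimapped": 0}
        for read in reads:
            hits = self.map_insert(read.insert)
            if len(hits) == 1:
                tid, pos = hits[0]
                rows.append((tid, pos, len(read.insert), read.umi))
                counts["mapped"] += 1
            elif not hits:
                counts["unmapped"] += 1
            else:
                counts["multimapped"] += 1
        df = pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)
        return df, counts


def dedup(footprints: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one representative per (transcript, pos5, length, UMI).

    The first occurrence in input order is retained, so output order is
    deterministic given input order, and the operation is idempotent.
    """
    return footprints.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)


def restrict_lengths(footprints: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only 20-22 nt (short) and 27-29 nt (long) reads, labeling the class."""
    mask = footprints["length"].isin(SUPPORTED_LENGTHS)
    kept = footprints[mask].copy().reset_index(drop=True)
    kept["length_class"] = kept["length"].map(length_class)
    counts = {
        "input": len(footprints),
        "kept": len(kept),
        "dropped_length": int((~mask).sum()),
    }
    return kept, counts


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    """Read a tabular alignment (transcript_id, pos5_0based, length, umi)."""
    df = pd.read_csv(path, sep="\t", dtype={"umi": str})
    df = df.rename(columns={"pos5_0based": "pos5"})
    required = set(FOOTPRINT_COLUMNS)
    if not required.issubset(df.columns):
        raise ValueError(f"alignment table {path} lacks columns {sorted(required - set(df.columns))}")
    return df[FOOTPRINT_COLUMNS]


def read_sam(path: str | Path) -> pd.DataFrame:
    """Read transcriptome-space alignments from SAM (primary, mapped only).

    The UMI is recovered from the trailing ``_<umi>`` of the query name
    when present (the convention used by the simulator's SAM writer);
    otherwise an empty UMI is recorded.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            name = aln.query_name or ""
            umi = name.rsplit("_", 1)[1] if "_" in name else ""
            rows.append(
                (aln.reference_name, aln.reference_start, aln.query_length, umi)
            )
    return pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)
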