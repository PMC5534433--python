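"""Synthetic transcriptomes and two-class ribosome footprint reads.

The generator emulates the structure of a yeast ribosome-profiling
library in transcript space: ORFs of configurable length, footprints of
the two conformational length classes (short 20-22 nt, long 27-29 nt)
whose 5' ends are back-computed from a sampled A-site codon through the
inverse of the length-specific offsets, a ligated linker carrying a
random barcode (UMI) and a fixed multiplex barcode, and an optional
fraction of injected PCR duplicates.

Stalling structure is planted three ways, all recorded as ground truth:

* :class:`StallSpec` — a (P-codon, A-codon) pair; every occurrence of the
  pair in any CDS multiplies the A-site dwell weight by the class
  fold-enrichment.  A configurable number of occurrences is planted
  explicitly into the sequences.
* :class:`SiteStall` — a single (transcript, codon) position, used to
  plant stalls at exact offsets (e.g. downstream of a polybasic tract,
  or inside a reporter insert).
* :class:`Attenuator` — multiplies dwell weights downstream of a
  boundary codon by a readthrough probability, emulating ribosomes lost
  at an arrest sequence.

Reads are error-free; sequencing-error models are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .asite import (
    DEFAULT_OFFSETS,
    SHORT,
    LONG,
    CLASSES,
    class_lengths,
    length_class,
    SUPPORTED_LENGTHS,
)
from .orfs import OrfRecord, write_orf_table, write_transcriptome_fasta

BASES = np.array(list("ACGT"))
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)
#: K/R codons used when planting polybasic tracts.  CGA is excluded so
#: tracts do not accidentally create CGA-CGA di-codons that interact
#: with pair-based stall specs.
TRACT_CODONS = ("AAA", "AAG", "AGA", "AGG", "CGT", "CGC", "CGG")

DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    20: 0.125, 21: 0.25, 22: 0.125,
    27: 0.125, 28: 0.25, 29: 0.125,
}

TRUTH_COLUMNS = ("transcript_id", "pos5_0based", "length", "umi")


def _codon_ok(codon: str) -> bool:
    return codon in SENSE_CODONS


@dataclass(frozen=True)
class StallSpec:
    """Fold-enrichment of dwell time at every occurrence of a P-A codon pair."""

    p_codon: str
    a_codon: str
    enrichment_short: float = 1.0
    enrichment_long: float = 1.0

    def __post_init__(self) -> None:
        for c in (self.p_codon, self.a_codon):
            if not _codon_ok(c):
                raise ValueError(f"{c!r} is not a valid sense codon")
        for e in (self.enrichment_short, self.enrichment_long):
            if not np.isfinite(e) or e < 1.0:
                raise ValueError(f"enrichment must be finite and >= 1, got {e}")

    def enrichment(self, cls: str) -> float:
        return self.enrichment_short if cls == SHORT else self.enrichment_long


@dataclass(frozen=True)
class SiteStall:
    """Fold-enrichment of dwell time at one exact codon position."""

    transcript_id: str
    codon_index: int
    enrichment_short: float = 1.0
    enrichment_long: float = 1.0

    def enrichment(self, cls: str) -> float:
        return self.enrichment_short if cls == SHORT else self.enrichment_long


@dataclass(frozen=True)
class Attenuator:
    """Scale dwell weights at codons >= boundary_codon by a readthrough probability."""

    transcript_id: str
    boundary_codon: int
    readthrough: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.readthrough <= 1.0:
            raise ValueError(f"readthrough must be in [0, 1], got {self.readthrough}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic library, driven by a single seed."""

    n_transcripts: int = 50
    codon_count_range: tuple[int, int] = (150, 300)
    mean_reads_per_codon: float = 2.0
    class_mixture: float = 0.5  # fraction of reads in the short class
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    stall_specs: list[StallSpec] = field(default_factory=list)
    site_stalls: list[SiteStall] = field(default_factory=list)
    attenuators: list[Attenuator] = field(default_factory=list)
    planted_per_spec: int = 50
    n_polybasic: int = 0
    tract_length: int = 10
    umi_length: int = 7  # 5 linker Ns + 2 RT Ns, collapsed into one tag
    sample_barcode: str = "ATCGT"
    linker_constant: str = "TGATCGGAAGAGCACACGTCTGAA"
    duplicate_fraction: float = 0.0
    read_length: int = 51
    utr_length: int = 20
    edge_exclude: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.class_mixture <= 1.0:
            raise ValueError("class_mixture must be in [0, 1]")
        lo, hi = self.codon_count_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad codon_count_range {self.codon_count_range}")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"length_distribution sums to {total}, expected 1")
        bad = set(self.length_distribution) - SUPPORTED_LENGTHS
        if bad:
            raise ValueError(f"length_distribution has unsupported lengths {sorted(bad)}")
        for cls in CLASSES:
            mass = sum(
                p for l, p in self.length_distribution.items() if length_class(l) == cls
            )
            if mass <= 0:
                raise ValueError(f"length_distribution gives zero mass to {cls} lengths")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")

    def class_length_probs(self, cls: str) -> tuple[tuple[int, ...], np.ndarray]:
        """Lengths of one class and their renormalized probabilities."""
        lengths = class_lengths(cls)
        p = np.array([self.length_distribution.get(l, 0.0) for l in lengths])
        return lengths, p / p.sum()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["codon_count_range"] = list(self.codon_count_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["codon_count_range"] = tuple(d["codon_count_range"])
        d["stall_specs"] = [StallSpec(**s) for s in d.get("stall_specs", [])]
        d["site_stalls"] = [SiteStall(**s) for s in d.get("site_stalls", [])]
        d["attenuators"] = [Attenuator(**a) for a in d.get("attenuators", [])]
        return cls(**d)


@dataclass
class SyntheticTranscriptome:
    """Generated ORFs plus the positions of everything planted into them."""

    orfs: list[OrfRecord]
    planted_pairs: list[tuple[str, int, int]]  # (transcript, A-codon index, spec index)
    polybasic_starts: list[tuple[str, int]]  # (transcript, tract start codon)

    def write(self, fasta_path: str | Path, table_path: str | Path) -> None:
        write_transcriptome_fasta(self.orfs, fasta_path)
        write_orf_table(self.orfs, table_path)


def _random_utr(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def simulate_transcriptome(config: SimulationConfig) -> SyntheticTranscriptome:
    """Generate random ORFs with planted stall pairs and polybasic tracts.

    Deterministic given ``config.seed``.  Transcripts are named
    ``T0000``, ``T0001``, ...; the first ``n_polybasic`` transcripts each
    carry one planted K/R tract of ``tract_length`` codons flanked by
    alanine runs, so the detected tract start (the first qualifying
    >=6-in-10 window) sits exactly 4 codons before the recorded planted
    block start.  Planted stall-pair occurrences are spread round-robin
    across transcripts at random interior positions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.codon_count_range

    if config.n_polybasic > config.n_transcripts:
        raise ValueError("n_polybasic exceeds n_transcripts")
    # a planted tract (and the first qualifying K/R window, which starts
    # 4 codons before the planted block) must sit a metagene window (25)
    # plus the edge exclusion (5) away from both ORF ends
    tract_margin = 36
    if config.n_polybasic > 0 and lo < 2 * tract_margin + config.tract_length:
        raise ValueError(
            f"codon_count_range {config.codon_count_range} too small to host a "
            f"{config.tract_length}-codon polybasic tract with margins"
        )

    # round-robin allocation of planted pair occurrences
    plants_per_transcript: list[list[int]] = [[] for _ in range(config.n_transcripts)]
    for spec_idx in range(len(config.stall_specs)):
        for j in range(config.planted_per_spec):
            plants_per_transcript[j % config.n_transcripts].append(spec_idx)

    orfs: list[OrfRecord] = []
    planted_pairs: list[tuple[str, int, int]] = []
    polybasic_starts: list[tuple[str, int]] = []

    for t in range(config.n_transcripts):
        tid = f"T{t:04d}"
        cc = int(rng.integers(lo, hi + 1))
        codons = list(rng.choice(SENSE_CODONS, size=cc))
        occupied: set[int] = set()

        if t < config.n_polybasic:
            s_lo, s_hi = tract_margin, cc - tract_margin - config.tract_length
            s = int(rng.integers(s_lo, s_hi + 1))
            for k in range(config.tract_length):
                codons[s + k] = str(rng.choice(TRACT_CODONS))
            # five Ala codons each side pin the first qualifying window:
            # a 10-residue window needs >= 6 K/R, so detection starts
            # deterministically 4 codons before the planted block
            for k in range(1, 6):
                codons[s - k] = "GCT"
                codons[s + config.tract_length + k - 1] = "GCT"
            occupied.update(range(s - 5, s + config.tract_length + 5))
            polybasic_starts.append((tid, s))

        for spec_idx in plants_per_transcript[t]:
            spec = config.stall_specs[spec_idx]
            if cc - config.edge_exclude - 1 <= config.edge_exclude + 1:
                raise ValueError(
                    f"transcript {tid} ({cc} codons) has no interior position for "
                    f"{spec.p_codon}-{spec.a_codon}; widen codon_count_range"
                )
            placed = False
            for _ in range(200):
                i = int(rng.integers(config.edge_exclude + 1, cc - config.edge_exclude - 1))
                if {i - 1, i, i + 1} & occupied:
                    continue
                codons[i - 1] = spec.p_codon
                codons[i] = spec.a_codon
                occupied.update((i - 1, i, i + 1))
                planted_pairs.append((tid, i, spec_idx))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place occurrence of {spec.p_codon}-{spec.a_codon} "
                    f"in transcript {tid} ({cc} codons); widen codon_count_range "
                    f"or reduce planted_per_spec"
                )

        cds = "".join(codons)
        seq = _random_utr(rng, config.utr_length) + cds + _random_utr(rng, config.utr_length)
        orfs.append(
            OrfRecord(
                transcript_id=tid,
                sequence=seq,
                cds_start=config.utr_length,
                cds_length=3 * cc,
            )
        )

    return SyntheticTranscriptome(orfs, planted_pairs, polybasic_starts)


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests.

    ``dwell_weights[(transcript, class)]`` is the unnormalized per-codon
    dwell weight used for read sampling (zero outside the interior).
    ``stall_sites`` lists every enriched position with its class
    fold-enrichments (both pair-driven and site-driven).
    """

    dwell_weights: dict[tuple[str, str], np.ndarray]
    stall_sites: pd.DataFrame  # transcript_id, codon_index, enrichment_short, enrichment_long, source
    counts: dict[str, int]


def _dwell_weights(
    orf: OrfRecord, cls: str, config: SimulationConfig
) -> tuple[np.ndarray, list[tuple[int, float, str]]]:
    cc = orf.codon_count
    e = config.edge_exclude
    w = np.zeros(cc)
    w[e : cc - e] = 1.0
    hits: list[tuple[int, float, str]] = []

    if config.stall_specs:
        lookup = {(s.p_codon, s.a_codon): s for s in config.stall_specs}
        codons = orf.codons()
        for i in range(max(1, e), cc - e):
            spec = lookup.get((codons[i - 1], codons[i]))
            if spec is not None:
                w[i] *= spec.enrichment(cls)
                hits.append((i, spec.enrichment(cls), "pair"))
    for st in config.site_stalls:
        if st.transcript_id == orf.transcript_id:
            if not e <= st.codon_index < cc - e:
                raise ValueError(
                    f"site stall at {st.transcript_id}:{st.codon_index} is outside "
                    f"the interior region [{e}, {cc - e})"
                )
            w[st.codon_index] *= st.enrichment(cls)
            hits.append((st.codon_index, st.enrichment(cls), "site"))
    for at in config.attenuators:
        if at.transcript_id == orf.transcript_id:
            w[at.boundary_codon :] *= at.readthrough
    return w, hits


@dataclass
class FootprintSimulation:
    """Simulated reads (including injected PCR duplicates) plus truth."""

    reads: pd.DataFrame  # transcript_id, pos5, length, umi, a_codon
    truth: SimulationTruth
    orfs: list[OrfRecord]
    config: SimulationConfig

    def write_truth_tsv(self, path: str | Path) -> None:
        out = self.reads.rename(columns={"pos5": "pos5_0based"})
        out[list(TRUTH_COLUMNS)].to_csv(path, sep="\t", index=False)

    def write_fastq(self, path: str | Path) -> None:
        """Raw reads: insert + UMI + multiplex barcode + linker, clipped to read_length."""
        seqs = {o.transcript_id: o.sequence for o in self.orfs}
        tail = self.config.sample_barcode + self.config.linker_constant
        with open(path, "w") as fh:
            for n, row in enumerate(self.reads.itertuples(index=False)):
                insert = seqs[row.transcript_id][row.pos5 : row.pos5 + row.length]
                seq = (insert + row.umi + tail)[: self.config.read_length]
                fh.write(f"@sim{n:07d}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_sam(self, path: str | Path) -> None:
        """Unsorted transcriptome-space SAM with perfect-match alignments."""
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for o in self.orfs:
                fh.write(f"@SQ\tSN:{o.transcript_id}\tLN:{len(o.sequence)}\n")
            seqs = {o.transcript_id: o.sequence for o in self.orfs}
            for n, row in enumerate(self.reads.itertuples(index=False)):
                insert = seqs[row.transcript_id][row.pos5 : row.pos5 + row.length]
                fh.write(
                    f"sim{n:07d}_{row.umi}\t0\t{row.transcript_id}\t{row.pos5 + 1}\t255\t"
                    f"{row.length}M\t*\t0\t0\t{insert}\t{'I' * row.length}\n"
                )


def simulate_footprints(
    source: SyntheticTranscriptome | Sequence[OrfRecord],
    config: SimulationConfig,
    offsets: Mapping[int, int] | None = None,
) -> FootprintSimulation:
    """Sample footprints from dwell-weight distributions over interior codons.

    Each read draws an A-site codon with weight 1 times any matching
    stall enrichment for its class, a length from the class-conditional
    length distribution, and its 5' position by inverting the A-site
    offset for that length: ``pos5 = cds_start + 3*k - offset(length)``.
    Total reads equal the configured depth exactly; UMIs are resampled
    on accidental key collision so that with ``duplicate_fraction == 0``
    every (transcript, pos5, length, UMI) tuple is unique.
    """
    config.validate()
    orfs = list(source.orfs if isinstance(source, SyntheticTranscriptome) else source)
    if not orfs:
        raise ValueError("no ORFs to simulate from")
    table = dict(DEFAULT_OFFSETS if offsets is None else offsets)
    rng = np.random.default_rng(config.seed + 1)  # independent of sequence stream

    dwell: dict[tuple[str, str], np.ndarray] = {}
    site_rows: list[dict] = []
    chunks: list[pd.DataFrame] = []
    n_resampled = 0

    for orf in orfs:
        cc = orf.codon_count
        if cc <= 2 * config.edge_exclude:
            continue  # no interior support
        n_reads = int(round(config.mean_reads_per_codon * cc))
        n_short = rng.binomial(n_reads, config.class_mixture)
        per_class = {SHORT: n_short, LONG: n_reads - n_short}
        seen_hits: dict[int, dict] = {}
        for cls in CLASSES:
            w, hits = _dwell_weights(orf, cls, config)
            dwell[(orf.transcript_id, cls)] = w
            for idx, enr, src in hits:
                row = seen_hits.setdefault(
                    idx,
                    {
                        "transcript_id": orf.transcript_id,
                        "codon_index": idx,
                        "enrichment_short": 1.0,
                        "enrichment_long": 1.0,
                        "source": src,
                    },
                )
                key = "enrichment_short" if cls == SHORT else "enrichment_long"
                row[key] = enr if row[key] == 1.0 else row[key] * enr
            n_c = per_class[cls]
            if n_c == 0 or w.sum() == 0:
                continue
            a_codon = rng.choice(cc, size=n_c, p=w / w.sum())
            lengths_dom, probs = config.class_length_probs(cls)
            lengths = rng.choice(lengths_dom, size=n_c, p=probs)
            pos5 = orf.cds_start + 3 * a_codon - np.vectorize(table.__getitem__)(lengths)
            # resample draws whose back-computed 5' end leaves the transcript
            bad = (pos5 < 0) | (pos5 + lengths > len(orf.sequence))
            while bad.any():
                n_resampled += int(bad.sum())
                a_codon[bad] = rng.choice(cc, size=int(bad.sum()), p=w / w.sum())
                lengths[bad] = rng.choice(lengths_dom, size=int(bad.sum()), p=probs)
                pos5 = orf.cds_start + 3 * a_codon - np.vectorize(table.__getitem__)(lengths)
                bad = (pos5 < 0) | (pos5 + lengths > len(orf.sequence))
            umis = np.array(
                ["".join(r) for r in BASES[rng.integers(0, 4, (n_c, config.umi_length))]]
            )
            chunks.append(
                pd.DataFrame(
                    {
                        "transcript_id": orf.transcript_id,
                        "pos5": pos5.astype(int),
                        "length": lengths.astype(int),
                        "umi": umis,
                        "a_codon": a_codon.astype(int),
                    }
                )
            )
        site_rows.extend(seen_hits.values())

    if not chunks:
        raise ValueError("simulation produced no reads; check depth and ORF lengths")
    reads = pd.concat(chunks, ignore_index=True)

    # enforce unique dedup keys, then inject duplicates deliberately
    key_cols = ["transcript_id", "pos5", "length", "umi"]
    n_umi_resampled = 0
    dup_mask = reads.duplicated(subset=key_cols, keep="first")
    while dup_mask.any():
        n = int(dup_mask.sum())
        n_umi_resampled += n
        reads.loc[dup_mask, "umi"] = [
            "".join(r) for r in BASES[rng.integers(0, 4, (n, config.umi_length))]
        ]
        dup_mask = reads.duplicated(subset=key_cols, keep="first")

    n_total = len(reads)
    n_dup = int(round(config.duplicate_fraction * n_total))
    if n_dup > 0:
        targets = rng.choice(n_total, size=n_dup, replace=False)
        pool = np.setdiff1d(np.arange(n_total), targets)
        donors = rng.choice(pool, size=n_dup, replace=True)
        reads.iloc[targets] = reads.iloc[donors].to_numpy()

    stall_sites = pd.DataFrame(
        site_rows,
        columns=[
            "transcript_id",
            "codon_index",
            "enrichment_short",
            "enrichment_long",
            "source",
        ],
    )
    truth = SimulationTruth(
        dwell_weights=dwell,
        stall_sites=stall_sites,
        counts={
            "depth": n_total,
            "duplicates_injected": n_dup,
            "out_of_bounds_resampled": n_resampled,
            "umi_collisions_resampled": n_umi_resampled,
        },
    )
    return FootprintSimulation(reads=reads, truth=truth, orfs=orfs, config=config)
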