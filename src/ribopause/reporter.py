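"""Reporter-transcript occupancy and readthrough quantification.

The reporter (e.g. GFP - R(CGN)12 arrest insert - FLAG - HIS3) is an
ordinary transcript in the transcriptome plus a segment annotation
giving codon intervals for the upstream ORF region, the arrest insert
and the downstream region.  Occupancy is the per-codon, per-class
A-site count vector; the readthrough index is the mean density of the
downstream segment divided by that of the upstream segment, excluding
five codons flanking each segment boundary so stall peaks at a boundary
do not contaminate segment means.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .asite import CLASSES

SEGMENT_COLUMNS = ("segment_name", "start_codon", "end_codon")
BOUNDARY_FLANK = 5


@dataclass(frozen=True)
class Segment:
    """Codon interval [start, end), 0-based half-open, within the reporter CDS."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"segment {self.name}: bad interval [{self.start}, {self.end})")


@dataclass
class ReporterModel:
    """Reporter transcript with ordered, non-overlapping segment annotations."""

    transcript_id: str
    segments: Sequence[Segment]
    insert_name: str

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        if self.insert_name not in names:
            raise ValueError(f"insert segment {self.insert_name!r} not annotated")
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"segments {a.name} and {b.name} overlap")
        self.segments = list(ordered)
        i = names.index(self.insert_name)
        if i == 0 or i == len(names) - 1:
            raise ValueError("insert segment must have upstream and downstream neighbours")

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def upstream_name(self) -> str:
        return self.segments[0].name

    @property
    def downstream_name(self) -> str:
        return self.segments[-1].name

    @classmethod
    def from_tsv(
        cls, path: str | Path, transcript_id: str, insert_name: str
    ) -> "ReporterModel":
        segments = []
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                segments.append(
                    Segment(row["segment_name"], int(row["start_codon"]), int(row["end_codon"]))
                )
        return cls(transcript_id, segments, insert_name)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(SEGMENT_COLUMNS)
            for s in self.segments:
                writer.writerow([s.name, s.start, s.end])


@dataclass
class OccupancyProfile:
    """Per-class A-site counts along the reporter CDS."""

    transcript_id: str
    counts: dict[str, np.ndarray]  # class -> vector over codons

    def peak(self, length_class: str) -> set[int]:
        """Argmax codon indices (a set when tied); empty set if no reads."""
        c = self.counts[length_class]
        if c.max() == 0:
            return set()
        return {int(i) for i in np.nonzero(c == c.max())[0]}

    def plot(self, model: "ReporterModel | None" = None, ax=None):
        """Per-class occupancy along the reporter, with segment boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cls, c in self.counts.items():
            ax.plot(np.arange(len(c)), c, label=cls, drawstyle="steps-mid")
        if model is not None:
            for seg in model.segments:
                ax.axvline(seg.start, color="grey", lw=0.5)
                ax.axvline(seg.end, color="grey", lw=0.5)
        ax.set_xlabel("codon along reporter CDS")
        ax.set_ylabel("A-site footprint count")
        ax.legend()
        return ax

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cls, c in self.counts.items():
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": self.transcript_id,
                        "codon_index": np.arange(len(c)),
                        "length_class": cls,
                        "count": c,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def reporter_occupancy(
    asite_calls: pd.DataFrame, model: ReporterModel, codon_count: int
) -> OccupancyProfile:
    """Per-codon, per-class counts of in-CDS A-site calls on the reporter."""
    calls = asite_calls[
        (asite_calls["transcript_id"] == model.transcript_id) & asite_calls["in_cds"]
    ]
    counts: dict[str, np.ndarray] = {}
    for cls in CLASSES:
        vec = np.zeros(codon_count)
        sel = calls[calls["length_class"] == cls]
        np.add.at(vec, sel["a_codon"].to_numpy().astype(int), 1)
        counts[cls] = vec
    return OccupancyProfile(model.transcript_id, counts)


def _segment_mean(vec: np.ndarray, seg: Segment, flank: int) -> float | None:
    lo, hi = seg.start + flank, seg.end - flank
    if hi <= lo:
        return None
    return float(vec[lo:hi].mean())


def readthrough_index(
    profile: OccupancyProfile,
    model: ReporterModel,
    upstream: str | None = None,
    downstream: str | None = None,
    flank: int = BOUNDARY_FLANK,
) -> dict[str, float | None]:
    """Downstream/upstream segment mean-density ratio, per class and combined.

    ``None`` flags an undefined index (zero upstream density or a
    segment too short for the boundary flank).  Defaults compare the
    first annotated segment with the last (e.g. GFP vs HIS3).
    """
    up = model.segment(upstream or model.upstream_name)
    down = model.segment(downstream or model.downstream_name)
    out: dict[str, float | None] = {}
    vectors: Mapping[str, np.ndarray] = dict(profile.counts)
    combined = sum(profile.counts.values())
    for label, vec in {**vectors, "combined": combined}.items():
        u = _segment_mean(vec, up, flank)
        d = _segment_mean(vec, down, flank)
        out[label] = None if not u else (d / u if d is not None else None)
    return out
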