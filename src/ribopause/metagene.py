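"""Polybasic-tract detection and metagene density profiles around tracts.

A polybasic tract is a stretch of protein sequence with six or more
arginine or lysine residues in a 10-residue window.  Overlapping
qualifying windows are merged into one tract anchored at the first
residue of its first qualifying window, so one biological tract yields
one metagene alignment point.

The metagene profile aligns per-codon footprint densities of one length
class at tract starts: each contributing tract's density row is
normalized by its host ORF's interior mean (so highly expressed genes
do not dominate) and rows are averaged position-wise over a symmetric
window.  Only tracts whose host ORF passes the density filter and whose
window fits inside the ORF interior contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .orfs import OrfRecord
from .pause import DensityProfile

KR = frozenset("KR")
KR_WINDOW = 10
MIN_KR = 6
METAGENE_WINDOW = 25


@dataclass(frozen=True)
class PolybasicTract:
    transcript_id: str
    start_codon_index: int  # first residue of the first qualifying window
    kr_count_in_window: int


def _qualifying_starts(protein: str, min_kr: int, window: int) -> list[int]:
    if len(protein) < window:
        return []
    flags = np.frombuffer(protein.encode(), dtype="S1")
    kr = (flags == b"K") | (flags == b"R")
    sums = np.convolve(kr.astype(int), np.ones(window, dtype=int), mode="valid")
    return [int(i) for i in np.nonzero(sums >= min_kr)[0]]


def detect_polybasic(
    orf: OrfRecord, min_kr: int = MIN_KR, window: int = KR_WINDOW
) -> list[PolybasicTract]:
    """Find K/R-rich tracts (>= min_kr in a `window`-residue window) in one ORF.

    Runs of overlapping qualifying windows (successive starts closer
    than the window width) merge into one tract.  Untranslatable CDSs
    (internal stop before the final codon) raise ValueError; use
    :func:`detect_all` to skip and report them.
    """
    if not orf.is_translatable():
        raise ValueError(f"{orf.transcript_id}: internal stop codon; CDS untranslatable")
    protein = orf.translation()
    starts = _qualifying_starts(protein, min_kr, window)
    tracts: list[PolybasicTract] = []
    run_start: int | None = None
    prev: int | None = None
    for s in starts:
        if run_start is None:
            run_start = s
        elif s - prev >= window:  # no overlap with previous qualifying window
            tracts.append(_tract(orf, protein, run_start, min_kr, window))
            run_start = s
        prev = s
    if run_start is not None:
        tracts.append(_tract(orf, protein, run_start, min_kr, window))
    return tracts


def _tract(
    orf: OrfRecord, protein: str, start: int, min_kr: int, window: int
) -> PolybasicTract:
    count = sum(1 for aa in protein[start : start + window] if aa in KR)
    return PolybasicTract(orf.transcript_id, start, count)


def detect_all(
    orfs: Iterable[OrfRecord], min_kr: int = MIN_KR, window: int = KR_WINDOW
) -> tuple[list[PolybasicTract], list[str]]:
    """Tracts across a transcriptome; returns (tracts, skipped transcript ids)."""
    tracts: list[PolybasicTract] = []
    skipped: list[str] = []
    for orf in orfs:
        if not orf.is_translatable():
            skipped.append(orf.transcript_id)
            continue
        tracts.extend(detect_polybasic(orf, min_kr, window))
    return tracts, skipped


@dataclass
class MetageneProfile:
    """Averaged normalized density at codon offsets relative to tract starts."""

    length_class: str
    positions: np.ndarray  # -W .. +W
    mean: np.ndarray  # NaN where no tract contributes
    n_tracts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_class": self.length_class,
                "rel_position": self.positions,
                "mean": self.mean,
                "n": self.n_tracts,
            }
        )

    def plot(self, ax=None):
        """Line plot of the profile (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.positions, self.mean, label=f"{self.length_class} (n={self.n_tracts})")
        ax.axhline(1.0, color="grey", lw=0.5)
        ax.set_xlabel("codons from tract start")
        ax.set_ylabel("normalized footprint density")
        ax.legend()
        return ax


def metagene_profile(
    profiles: Mapping[tuple[str, str], DensityProfile],
    tracts: Iterable[PolybasicTract],
    length_class: str,
    window: int = METAGENE_WINDOW,
) -> MetageneProfile:
    """Position-wise mean of tract-aligned, interior-mean-normalized density.

    ``profiles`` should already be density-filtered; tracts whose host
    ORF is absent from it, or whose +/- window leaves the ORF interior,
    are dropped.
    """
    rows = []
    for tract in tracts:
        prof = profiles.get((tract.transcript_id, length_class))
        if prof is None:
            continue
        lo = tract.start_codon_index - window
        hi = tract.start_codon_index + window
        interior = prof.interior
        if lo < interior.start or hi > interior.stop - 1:
            continue
        mean = prof.interior_mean
        if mean <= 0:
            continue
        rows.append(prof.counts[lo : hi + 1] / mean)
    positions = np.arange(-window, window + 1)
    if not rows:
        warnings.warn(f"no tracts contribute to the {length_class} metagene profile", stacklevel=2)
        return MetageneProfile(length_class, positions, np.full(2 * window + 1, np.nan), 0)
    stack = np.vstack(rows)
    return MetageneProfile(length_class, positions, stack.mean(axis=0), len(rows))
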