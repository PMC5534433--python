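"""Per-codon pause scores and class-stratified di-codon statistics.

A codon's pause score is its A-site footprint count divided by the mean
footprint density over the ORF interior (all codons except the first
and last five).  ORFs with interior mean density below 0.5
footprints/codon are excluded ("0.5 and more" is inclusive), as are
ORFs too short to have an interior.  Scores are computed per footprint
length class independently by default — the short-footprint analysis
sees only short reads — since the two classes report different ribosome
conformations; a combined-class denominator is available as an option.

A di-codon occurrence is an interior codon position ``i`` with the pair
(codon[i-1], codon[i]) at the (P, A) sites; the occurrence is attributed
the A-site codon's pause score, and the table averages occurrences
(unweighted) across all retained ORFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .asite import CLASSES
from .orfs import OrfRecord, orf_index

EDGE_EXCLUDE = 5
MIN_DENSITY = 0.5
MIN_OCCURRENCES = 5


@dataclass
class DensityProfile:
    """Per-(transcript, class) codon-resolution A-site count vector."""

    transcript_id: str
    length_class: str
    counts: np.ndarray
    edge_exclude: int = EDGE_EXCLUDE

    @property
    def codon_count(self) -> int:
        return len(self.counts)

    @property
    def interior(self) -> slice:
        """Codons [edge_exclude, codon_count - edge_exclude), 0-based."""
        return slice(self.edge_exclude, self.codon_count - self.edge_exclude)

    @property
    def interior_mean(self) -> float:
        return float(self.counts[self.interior].mean())

    def passes_filter(self, min_density: float = MIN_DENSITY) -> bool:
        return self.interior_mean >= min_density


def build_density_profiles(
    asite_calls: pd.DataFrame,
    orfs: Iterable[OrfRecord] | Mapping[str, OrfRecord],
    edge_exclude: int = EDGE_EXCLUDE,
) -> tuple[dict[tuple[str, str], DensityProfile], list[str]]:
    """Accumulate in-CDS A-site calls into per-(transcript, class) profiles.

    A profile is built for every (annotated ORF, class) combination, so
    zero-coverage profiles exist and can fail the density filter
    explicitly.  ORFs with no interior (codon_count <= 2*edge_exclude)
    are excluded and returned in the report list.
    """
    index = orfs if isinstance(orfs, Mapping) else orf_index(orfs)
    excluded = [t for t, o in index.items() if o.codon_count <= 2 * edge_exclude]
    usable = {t: o for t, o in index.items() if t not in set(excluded)}

    calls = asite_calls[asite_calls["in_cds"]]
    profiles: dict[tuple[str, str], DensityProfile] = {}
    for tid, orf in usable.items():
        for cls in CLASSES:
            profiles[(tid, cls)] = DensityProfile(
                tid, cls, np.zeros(orf.codon_count), edge_exclude
            )
    grouped = calls.groupby(["transcript_id", "length_class"], sort=False)
    for (tid, cls), group in grouped:
        prof = profiles.get((tid, cls))
        if prof is None:
            continue  # ORF excluded for lacking an interior
        np.add.at(prof.counts, group["a_codon"].to_numpy(), 1)
    return profiles, excluded


def combine_classes(
    profiles: Mapping[tuple[str, str], DensityProfile]
) -> dict[tuple[str, str], DensityProfile]:
    """Optional combined-class density: both classes share one summed profile."""
    combined: dict[tuple[str, str], DensityProfile] = {}
    tids = {tid for tid, _ in profiles}
    for tid in tids:
        total = sum(profiles[(tid, cls)].counts for cls in CLASSES)
        for cls in CLASSES:
            p = profiles[(tid, cls)]
            combined[(tid, cls)] = DensityProfile(tid, cls, np.asarray(total, float), p.edge_exclude)
    return combined


def filter_orfs(
    profiles: Mapping[tuple[str, str], DensityProfile],
    min_density: float = MIN_DENSITY,
) -> dict[tuple[str, str], DensityProfile]:
    """Keep profiles with interior mean density >= min_density (inclusive)."""
    return {k: p for k, p in profiles.items() if p.passes_filter(min_density)}


def pause_scores(profile: DensityProfile) -> pd.DataFrame:
    """Pause score per interior codon: count / interior mean density.

    Edge codons are excluded rather than scored.  Requires a profile
    that passes the density filter (positive interior mean).
    """
    mean = profile.interior_mean
    if mean <= 0:
        raise ValueError(
            f"{profile.transcript_id}/{profile.length_class}: interior mean is 0; "
            "filter profiles before scoring"
        )
    idx = np.arange(profile.codon_count)[profile.interior]
    counts = profile.counts[profile.interior]
    return pd.DataFrame(
        {
            "transcript_id": profile.transcript_id,
            "codon_index": idx,
            "length_class": profile.length_class,
            "count": counts,
            "score": counts / mean,
        }
    )


def pause_score_table(
    profiles: Mapping[tuple[str, str], DensityProfile]
) -> pd.DataFrame:
    """Concatenated pause scores for all (already filtered) profiles."""
    frames = [pause_scores(p) for p in profiles.values()]
    if not frames:
        return pd.DataFrame(
            columns=["transcript_id", "codon_index", "length_class", "count", "score"]
        )
    return pd.concat(frames, ignore_index=True)


class DicodonScoreTable:
    """Averaged pause scores per (P codon, A codon, length class).

    Occurrence-level scores are retained (``occurrences``) so dispersion
    can be computed; ``summary`` aggregates to mean/sd/n, and pairs with
    zero occurrences are absent rather than zero-filled.
    """

    def __init__(self, occurrences: pd.DataFrame):
        self.occurrences = occurrences

    def summary(self, min_occurrences: int = MIN_OCCURRENCES) -> pd.DataFrame:
        if self.occurrences.empty:
            return pd.DataFrame(
                columns=["p_codon", "a_codon", "length_class", "n", "mean", "sd", "low_n"]
            )
        g = self.occurrences.groupby(["p_codon", "a_codon", "length_class"], sort=True)
        out = g["score"].agg(n="size", mean="mean", sd="std").reset_index()
        out["n"] = out["n"].astype(int)
        out["low_n"] = out["n"] < min_occurrences
        return out

    def rank(
        self,
        length_class: str,
        top_n: int | None = 10,
        min_occurrences: int = MIN_OCCURRENCES,
    ) -> pd.DataFrame:
        """Top di-codons of one class, descending by mean pause score.

        Ties break by higher occurrence count, then lexicographic pair.
        Pairs below ``min_occurrences`` are not ranked; ``top_n=None``
        returns the full ranking.
        """
        s = self.summary(min_occurrences)
        s = s[(s["length_class"] == length_class) & (~s["low_n"])]
        s = s.sort_values(
            ["mean", "n", "p_codon", "a_codon"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        if top_n is None:
            return s
        if top_n > len(s):
            warnings.warn(
                f"requested top {top_n} di-codons but only {len(s)} available",
                stacklevel=2,
            )
        return s.head(top_n)


def dicodon_scores(
    profiles: Mapping[tuple[str, str], DensityProfile],
    orfs: Iterable[OrfRecord] | Mapping[str, OrfRecord],
) -> DicodonScoreTable:
    """Collect per-occurrence di-codon pause scores over retained profiles."""
    index = orfs if isinstance(orfs, Mapping) else orf_index(orfs)
    rows = []
    for (tid, cls), profile in profiles.items():
        orf = index[tid]
        codons = orf.codons()
        scores = pause_scores(profile)
        idx = scores["codon_index"].to_numpy()
        sc = scores["score"].to_numpy()
        valid = idx >= 1  # P-site must exist
        for i, s in zip(idx[valid], sc[valid]):
            rows.append((codons[i - 1], codons[i], cls, tid, int(i), float(s)))
    occurrences = pd.DataFrame(
        rows,
        columns=["p_codon", "a_codon", "length_class", "transcript_id", "codon_index", "score"],
    )
    return DicodonScoreTable(occurrences)


def rank_dicodons(
    table: DicodonScoreTable,
    length_class: str,
    top_n: int = 10,
    min_occurrences: int = MIN_OCCURRENCES,
) -> pd.DataFrame:
    return table.rank(length_class, top_n=top_n, min_occurrences=min_occurrences)
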