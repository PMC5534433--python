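"""A-site assignment from footprint 5' ends.

Short (20-22 nt) footprints come from rotated-state ribosomes, long
(27-29 nt) footprints from classical-state ribosomes.  Each analyzed
length has a fixed empirical offset from the read 5' end to the first
nucleotide of the A-site codon:

    length : 20  21  22  27  28  29
    offset : 15  15  16  14  15  16

The codon index is the floor of ``(pos5 + offset - cds_start) / 3``;
no sub-codon frame snapping is attempted, matching the codon-resolution
claims of the analysis.  The P-site codon is the A-site codon minus one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .orfs import OrfRecord, orf_index

#: 5'-end -> A-site offsets (nt), keyed by footprint length.
DEFAULT_OFFSETS: dict[int, int] = {20: 15, 21: 15, 22: 16, 27: 14, 28: 15, 29: 16}

SHORT_LENGTHS = frozenset({20, 21, 22})
LONG_LENGTHS = frozenset({27, 28, 29})
SUPPORTED_LENGTHS = SHORT_LENGTHS | LONG_LENGTHS

SHORT = "short"
LONG = "long"
CLASSES = (SHORT, LONG)


class UnsupportedLength(ValueError):
    """Raised for footprint lengths outside the two analyzed classes."""


def length_class(length: int) -> str:
    """Return ``"short"`` for 20-22 nt reads, ``"long"`` for 27-29 nt."""
    if length in SHORT_LENGTHS:
        return SHORT
    if length in LONG_LENGTHS:
        return LONG
    raise UnsupportedLength(f"footprint length {length} nt is outside 20-22 / 27-29")


def class_lengths(cls: str) -> tuple[int, ...]:
    if cls == SHORT:
        return (20, 21, 22)
    if cls == LONG:
        return (27, 28, 29)
    raise ValueError(f"unknown length class {cls!r}")


def assign_offset(length: int, offsets: Mapping[int, int] | None = None) -> int:
    """A-site offset (nt from the 5' end) for a supported footprint length."""
    table = DEFAULT_OFFSETS if offsets is None else offsets
    try:
        return table[length]
    except KeyError:
        raise UnsupportedLength(
            f"no A-site offset for footprint length {length} nt"
        ) from None


@dataclass(frozen=True)
class AsiteCall:
    """A-site (and P-site) codon assignment for one footprint."""

    transcript_id: str
    a_codon_index: int
    length_class: str
    in_cds: bool

    @property
    def p_codon_index(self) -> int:
        return self.a_codon_index - 1

    @property
    def p_valid(self) -> bool:
        """P-site usable for di-codon statistics (A-site not at codon 0)."""
        return self.in_cds and self.a_codon_index >= 1


def read_to_asite(
    pos5: int,
    length: int,
    orf: OrfRecord,
    offsets: Mapping[int, int] | None = None,
) -> AsiteCall:
    """Convert one aligned footprint to its A-site codon index."""
    a_nt = pos5 + assign_offset(length, offsets)
    a_codon = (a_nt - orf.cds_start) // 3  # floor division, also for negatives
    return AsiteCall(
        transcript_id=orf.transcript_id,
        a_codon_index=int(a_codon),
        length_class=length_class(length),
        in_cds=0 <= a_codon < orf.codon_count,
    )


def map_asites(
    footprints: pd.DataFrame,
    orfs: Iterable[OrfRecord] | dict[str, OrfRecord],
    offsets: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Vectorized A-site assignment for a footprint table.

    Parameters
    ----------
    footprints : DataFrame
        Columns ``transcript_id``, ``pos5``, ``length`` (all supported
        lengths; run length restriction first).
    orfs : iterable of OrfRecord or dict
        Annotation providing ``cds_start`` and ``codon_count``.

    Returns
    -------
    DataFrame with the input columns plus ``length_class``, ``a_codon``,
    ``p_codon`` and ``in_cds``.  Out-of-CDS calls are retained with
    ``in_cds == False`` so callers can tally them; downstream counting
    uses only ``in_cds`` rows.
    """
    index = orfs if isinstance(orfs, dict) else orf_index(orfs)
    table = DEFAULT_OFFSETS if offsets is None else dict(offsets)

    df = footprints.copy()
    unknown = set(df["length"].unique()) - set(table)
    if unknown:
        raise UnsupportedLength(f"no A-site offset for lengths {sorted(unknown)}")
    missing = set(df["transcript_id"].unique()) - set(index)
    if missing:
        raise ValueError(f"footprints reference unannotated transcripts {sorted(missing)}")

    offset = df["length"].map(table).to_numpy()
    cds_start = df["transcript_id"].map({t: o.cds_start for t, o in index.items()}).to_numpy()
    codon_count = df["transcript_id"].map({t: o.codon_count for t, o in index.items()}).to_numpy()

    a_nt = df["pos5"].to_numpy() + offset
    a_codon = np.floor_divide(a_nt - cds_start, 3)
    if "length_class" not in df.columns:
        df["length_class"] = df["length"].map(length_class)
    df["a_codon"] = a_codon
    df["p_codon"] = a_codon - 1
    df["in_cds"] = (a_codon >= 0) & (a_codon < codon_count)
    return df
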