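"""Mean per-position property profiles along TSS-aligned sequence sets.

Every length-k window of every sequence is scored with a k-mer property
table and the scores are averaged over sequences at each window position.
Window positions are labelled by the base immediately 3' of the central
phosphodiester bond — the (k/2 + 1)-th base of the window — so a 60-nt set
labelled −50…+10 yields 59 dinucleotide labels −49…+10, 57 tetranucleotide
labels −48…+9 and 55 hexanucleotide labels −47…+8, with the bond-spanning
windows (−1,+1), (−2,−1,+1,+2) and (−3,−2,−1,+1,+2,+3) all labelled +1.

The "upper" strand is the input sequence itself (5'→3' toward the TSS,
complementary to the template); the lower (template) strand is always
derived by reverse complementation, never read from input. Per-strand
tables are looked up through the reverse complement for the lower strand;
duplex-step tables give identical profiles on both strands by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._coding import window_codes
from .kmer_tables import DUPLEX_STEP, KmerPropertyTable
from .seqset_io import PromoterSet

__all__ = [
    "PositionProfile",
    "assign_window_labels",
    "property_profile",
    "strand_difference_profile",
]


@dataclass
class PositionProfile:
    """Per-position statistic with signed position labels.

    ``values`` may contain NaN where no window contributed (all-N columns);
    NaN is written as "NA" in TSV output, never as 0.
    """

    labels: np.ndarray
    values: np.ndarray
    n_eff: np.ndarray
    strand: str = "upper"
    table_name: str = ""
    units: str = ""
    subset: str | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=int)
        if not len(self.labels) == len(self.values) == len(self.n_eff):
            raise ValueError("labels, values and n_eff must have equal length")

    def value_at(self, label: int) -> float:
        hits = np.flatnonzero(self.labels == label)
        if len(hits) != 1:
            raise KeyError(f"label {label:+d} not in profile")
        return float(self.values[hits[0]])

    def argmin_label(self) -> int:
        return int(self.labels[np.nanargmin(self.values)])

    def argmax_label(self) -> int:
        return int(self.labels[np.nanargmax(self.values)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": [f"{p:+d}" for p in self.labels],
                "value": self.values,
                "n_eff": self.n_eff,
                "strand": self.strand,
                "table": self.table_name,
            }
        )
        if self.subset is not None:
            df["subset"] = self.subset
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA",
                               float_format="%.10g")


def assign_window_labels(k: int, set_labels: Sequence[int]) -> np.ndarray:
    """Signed labels for all length-k windows of a labelled sequence.

    The window starting at 0-based index j (covering j…j+k−1) is labelled
    with the position of its (k/2 + 1)-th base, the base 3' of the central
    bond. k must be even (an odd window has no central bond).
    """
    set_labels = np.asarray(set_labels, dtype=int)
    if k % 2 != 0:
        raise ValueError(f"k={k} is odd: a window without a central bond")
    if not 2 <= k <= len(set_labels):
        raise ValueError(f"k={k} outside 2..{len(set_labels)}")
    return set_labels[k // 2 : len(set_labels) - k + 1 + k // 2]


def _profile_arrays(
    pset: PromoterSet, table: KmerPropertyTable, lookup: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    codes = window_codes(pset.codes, table.k)
    valid = codes >= 0
    vals = np.where(valid, lookup[codes], 0.0)
    n_eff = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_eff > 0, vals.sum(axis=0) / np.maximum(n_eff, 1), np.nan)
    return means, n_eff


def property_profile(
    pset: PromoterSet, table: KmerPropertyTable, strand: str = "upper"
) -> PositionProfile:
    """Mean table value of every window position, on one strand.

    Windows containing N are excluded from both the numerator and the
    position's ``n_eff``; a position where every window is invalid gets NaN.
    """
    if strand not in ("upper", "lower"):
        raise ValueError(f"strand must be 'upper' or 'lower', got {strand!r}")
    if len(pset) == 0:
        raise ValueError("empty promoter set")
    lookup = table.values if strand == "upper" else table.lower_strand_values
    means, n_eff = _profile_arrays(pset, table, lookup)
    return PositionProfile(
        labels=assign_window_labels(table.k, pset.labels),
        values=means,
        n_eff=n_eff,
        strand=strand,
        table_name=table.name,
        units=table.units,
    )


def strand_difference_profile(
    pset: PromoterSet, table: KmerPropertyTable
) -> PositionProfile:
    """Upper-strand minus lower-strand profile, positionwise.

    Identically zero for duplex-step tables, which carry no strand
    information.
    """
    upper = property_profile(pset, table, "upper")
    if table.strand_semantics == DUPLEX_STEP:
        values = np.zeros_like(upper.values)
    else:
        lower = property_profile(pset, table, "lower")
        values = upper.values - lower.values
    return PositionProfile(
        labels=upper.labels,
        values=values,
        n_eff=upper.n_eff,
        strand="difference",
        table_name=table.name,
        units=table.units,
    )
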