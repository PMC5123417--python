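"""Motif-presence partitions of a promoter set and comparative profiles.

The canonical use is the literal-TATA split: a promoter is "TATA-containing"
if the tetranucleotide TATA occurs anywhere on the upper strand, else
"TATA-less". (This is not the same as lacking the full TATAWAAR consensus —
the split is by literal word presence.)
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .composition_profiles import motif_matches
from .kmer_tables import KmerPropertyTable
from .property_profiles import PositionProfile, property_profile
from .seqset_io import PromoterSet

__all__ = ["SubsetSplit", "split_by_motif", "split_percentages", "subset_profiles"]


def split_percentages(n_with: int, n_total: int) -> tuple[float, float]:
    """(pct_with, pct_without) of a partition, rounded half-up to 2 decimals."""
    if not 0 <= n_with <= n_total or n_total == 0:
        raise ValueError(f"invalid counts {n_with}/{n_total}")

    def pct(n: int) -> float:
        return float(
            (Decimal(100 * n) / Decimal(n_total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )

    return pct(n_with), pct(n_total - n_with)


@dataclass
class SubsetSplit:
    """Disjoint, exhaustive partition of a set by motif presence."""

    with_motif: PromoterSet
    without_motif: PromoterSet
    motif: str

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_with, n_without, n_total)."""
        return len(self.with_motif), len(self.without_motif), (
            len(self.with_motif) + len(self.without_motif)
        )

    @property
    def percentages(self) -> tuple[float, float]:
        n_with, _, n_total = self.counts
        return split_percentages(n_with, n_total)


def split_by_motif(
    pset: PromoterSet, motif: str, both_strands: bool = False
) -> SubsetSplit:
    """Partition by presence of an IUPAC motif at ≥1 window (overlaps allowed).

    Search is on the upper strand by default; ``both_strands=True`` also
    accepts a match anywhere on the reverse complement.
    """
    present = motif_matches(pset, motif).any(axis=1)
    if both_strands:
        from .kmer_tables import revcomp

        rc = PromoterSet(
            [revcomp(s) for s in pset.sequences], pset.length, pset.tss_offset
        )
        present |= motif_matches(rc, motif).any(axis=1)
    return SubsetSplit(
        with_motif=pset.subset(present),
        without_motif=pset.subset(~present),
        motif=motif.upper(),
    )


def subset_profiles(
    split: SubsetSplit, table: KmerPropertyTable
) -> dict[str, dict[str, PositionProfile]]:
    """Per-strand property profiles of each subset, tagged with its identity.

    Returns ``{"with_motif": {"upper": …, "lower": …}, "without_motif": …}``.
    """
    out: dict[str, dict[str, PositionProfile]] = {}
    for tag, subset in (
        ("with_motif", split.with_motif),
        ("without_motif", split.without_motif),
    ):
        if len(subset) == 0:
            raise ValueError(
                f"subset {tag!r} is empty for motif {split.motif}; "
                "check the motif against the sequence set"
            )
        out[tag] = {}
        for strand in ("upper", "lower"):
            prof = property_profile(subset, table, strand)
            prof.subset = tag
            out[tag][strand] = prof
    return out
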