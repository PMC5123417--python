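"""Built-in k-mer property tables.

The ultrasonic cleavage tables shipped here are SYNTHETIC stand-ins for the
experimentally measured dinucleotide (R) and tetranucleotide (T) relative
cleavage-intensity tables, which are distributed as journal supplementary
material and are not redistributed with this package. The stand-ins are
additive models anchored exactly to the four measured values quoted in the
literature text — R(CA)=1.130, R(TG)=0.900, T(ACGA)=1.537, T(TCGT)=1.263 —
and built so that cytosine-led steps cleave fastest and weak (A/T-rich)
contexts cleave slowest, matching the qualitative direction of the
measurements (pyrimidine sugars repucker fastest; W-rich TATA regions show
depressed cleavage). Absolute values outside the four anchors carry no
experimental meaning.

The DNase I hexamer table is likewise a synthetic minor-groove-geometry
proxy: W-rich (A-tract-like) hexamers, which narrow the minor groove, get
low cleavage values; a small purine/pyrimidine term makes the table
strand-asymmetric, as a single-strand cleavage index must be.
"""

from __future__ import annotations

import numpy as np

from ._coding import all_kmers
from .kmer_tables import (
    DUPLEX_STEP,
    PER_STRAND,
    KmerPropertyTable,
    derive_s_table,
    revcomp,
)

__all__ = [
    "synthetic_ultrasonic_r_table",
    "synthetic_ultrasonic_t_table",
    "synthetic_ultrasonic_s_table",
    "synthetic_dnase_hexamer_table",
    "synthetic_duplex_step_table",
    "builtin_table",
    "BUILTIN_TABLES",
]

# additive R model: R(n1 n2) = base5(n1) + context3(n2)
_R_BASE5 = {"A": 0.80, "C": 1.10, "G": 0.95, "T": 0.88}
_R_CTX3 = {"A": 0.03, "C": 0.05, "G": 0.02, "T": 0.01}

# additive flank model: T(n1 n2 n3 n4) = left(n1) + R(n2 n3) + right(n4)
_T_LEFT = {"A": 0.30, "C": 0.05, "G": 0.00, "T": 0.11}
_T_RIGHT = {"A": 0.117, "C": 0.00, "G": 0.05, "T": 0.033}


def synthetic_ultrasonic_r_table() -> KmerPropertyTable:
    """Synthetic dinucleotide ultrasonic cleavage index (R), per strand.

    Anchors: R(CA) = 1.130, R(TG) = 0.900.
    """
    mapping = {
        w: round(_R_BASE5[w[0]] + _R_CTX3[w[1]], 3) for w in all_kmers(2)
    }
    return KmerPropertyTable.from_dict(
        2, mapping, name="ultrasonic_R_synthetic", units="relative intensity",
        strand_semantics=PER_STRAND,
    )


def synthetic_ultrasonic_t_table() -> KmerPropertyTable:
    """Synthetic tetranucleotide ultrasonic cleavage index (T), per strand.

    Anchors: T(ACGA) = 1.537, T(TCGT) = 1.263. The central-step term equals
    the synthetic R table, so S = T − R isolates the flank contribution.
    """
    r = synthetic_ultrasonic_r_table()
    mapping = {
        w: round(_T_LEFT[w[0]] + r[w[1:3]] + _T_RIGHT[w[3]], 3)
        for w in all_kmers(4)
    }
    return KmerPropertyTable.from_dict(
        4, mapping, name="ultrasonic_T_synthetic", units="relative intensity",
        strand_semantics=PER_STRAND,
    )


def synthetic_ultrasonic_s_table() -> KmerPropertyTable:
    """S = T − R(centre) on the synthetic ultrasonic tables."""
    return derive_s_table(
        synthetic_ultrasonic_t_table(), synthetic_ultrasonic_r_table()
    )


def synthetic_dnase_hexamer_table() -> KmerPropertyTable:
    """Synthetic hexanucleotide DNase I cleavage index, per strand.

    value = 1 + 0.3·(#S − #W)/6 + 0.1·(#R − #Y)/6 over the hexamer: W-rich
    words (narrow minor groove) cleave least; the purine term breaks
    reverse-complement symmetry.
    """
    mapping = {}
    for w in all_kmers(6):
        n_w = sum(ch in "AT" for ch in w)
        n_r = sum(ch in "AG" for ch in w)
        mapping[w] = round(
            1.0 + 0.3 * ((6 - n_w) - n_w) / 6 + 0.1 * (n_r - (6 - n_r)) / 6, 6
        )
    return KmerPropertyTable.from_dict(
        6, mapping, name="dnase_hexamer_synthetic", units="relative intensity",
        strand_semantics=PER_STRAND,
    )


# toy stacking-energy-like values (kcal/mol scale) on the 10 canonical steps
_DUPLEX_CANONICAL = {
    "AA": -5.4, "AC": -10.5, "AG": -6.8, "AT": -6.6, "CA": -6.6,
    "CC": -8.3, "CG": -9.6, "GA": -9.8, "GC": -14.6, "TA": -3.8,
}


def synthetic_duplex_step_table() -> KmerPropertyTable:
    """Toy duplex base-pair-step table (10 unique values, revcomp-closed)."""
    mapping = dict(_DUPLEX_CANONICAL)
    for w in all_kmers(2):
        if w not in mapping:
            mapping[w] = mapping[revcomp(w)]
    return KmerPropertyTable.from_dict(
        2, mapping, name="stacking_energy_toy", units="kcal/mol",
        strand_semantics=DUPLEX_STEP,
    )


BUILTIN_TABLES = {
    "ultrasonic_r": synthetic_ultrasonic_r_table,
    "ultrasonic_t": synthetic_ultrasonic_t_table,
    "ultrasonic_s": synthetic_ultrasonic_s_table,
    "dnase_hexamer": synthetic_dnase_hexamer_table,
    "duplex_step_toy": synthetic_duplex_step_table,
}


def builtin_table(name: str) -> KmerPropertyTable:
    """Fetch a built-in table by short name (see BUILTIN_TABLES)."""
    try:
        return BUILTIN_TABLES[name]()
    except KeyError:
        raise ValueError(
            f"unknown built-in table {name!r}; one of {sorted(BUILTIN_TABLES)}"
        ) from None
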