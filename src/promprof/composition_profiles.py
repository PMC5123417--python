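"""Positional nucleotide-composition statistics.

k-mer frequency profiles (optionally over the collapsed purine/pyrimidine
or weak/strong alphabets), the per-position standard deviation of the
dinucleotide distribution, and positional motif-occurrence profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from ._coding import N_CODE, window_codes
from .property_profiles import PositionProfile
from .seqset_io import PromoterSet

__all__ = [
    "FrequencyProfile",
    "frequency_profile",
    "dinucleotide_sd_profile",
    "motif_occurrence_profile",
    "IUPAC_CLASSES",
]

# IUPAC nucleotide classes; Y = pyrimidine (Py), R = purine (Pu),
# W = weak (A/T), S = strong (G/C)
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# collapsed alphabets: base-code (ACGTN order) -> class code; class letters
_ALPHABETS = {
    "ACGT": (np.array([0, 1, 2, 3, N_CODE], dtype=np.uint8), "ACGT"),
    # purine (R: A,G) = 0, pyrimidine (Y: C,T) = 1
    "PyPu": (np.array([0, 1, 0, 1, N_CODE], dtype=np.uint8), "RY"),
    # weak (W: A,T) = 0, strong (S: G,C) = 1
    "WS": (np.array([0, 1, 1, 0, N_CODE], dtype=np.uint8), "WS"),
}


@dataclass
class FrequencyProfile:
    """categories × positions frequency matrix with position labels.

    Columns sum to 1 (fraction units) or 100 (percent) wherever at least
    one sequence contributed (``n_eff > 0``).
    """

    labels: np.ndarray
    categories: list[str]
    freq: np.ndarray
    n_eff: np.ndarray
    units: str = "fraction"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=int)
        if self.freq.shape != (len(self.categories), len(self.labels)):
            raise ValueError("freq must be categories × positions")

    def row(self, category: str) -> np.ndarray:
        return self.freq[self.categories.index(category)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.freq.T, columns=self.categories,
            index=[f"{p:+d}" for p in self.labels],
        )
        df.index.name = "position"
        df["n_eff"] = self.n_eff
        return df.reset_index()

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA",
                               float_format="%.10g")


def _window_labels(k: int, set_labels: np.ndarray) -> np.ndarray:
    # one rule for every k: label at the base with window offset k//2 —
    # the base itself for k=1, the base 3' of the central bond for even k,
    # the middle base for odd k
    return np.asarray(set_labels, dtype=int)[k // 2 : len(set_labels) - k + 1 + k // 2]


def frequency_profile(
    pset: PromoterSet, k: int = 1, alphabet: str = "ACGT", units: str = "fraction"
) -> FrequencyProfile:
    """Positional frequencies of every k-length word.

    Bases are first collapsed when ``alphabet`` is "PyPu" (purine R /
    pyrimidine Y) or "WS" (weak/strong), giving 2^k classes instead of 4^k
    words. Windows containing N are excluded from the numerator and from
    the position's ``n_eff``.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}; one of {list(_ALPHABETS)}")
    if units not in ("fraction", "percent"):
        raise ValueError(f"units must be 'fraction' or 'percent', got {units!r}")
    if not 1 <= k <= pset.length:
        raise ValueError(f"k={k} outside 1..{pset.length}")
    if len(pset) == 0:
        raise ValueError("empty promoter set")

    mapping, letters = _ALPHABETS[alphabet]
    radix = len(set(letters))
    codes = window_codes(pset.codes, k, mapping=mapping if alphabet != "ACGT" else None)
    n_cat = radix**k
    n_pos = codes.shape[1]
    counts = np.zeros((n_cat, n_pos), dtype=np.int64)
    for j in range(n_pos):
        col = codes[:, j]
        col = col[col >= 0]
        counts[:, j] = np.bincount(col, minlength=n_cat)
    n_eff = (codes >= 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_eff > 0, counts / np.maximum(n_eff, 1), np.nan)
    if units == "percent":
        freq = freq * 100.0
    categories = ["".join(w) for w in product(letters, repeat=k)]
    return FrequencyProfile(
        labels=_window_labels(k, pset.labels),
        categories=categories,
        freq=freq,
        n_eff=n_eff,
        units=units,
    )


def dinucleotide_sd_profile(pset: PromoterSet, ddof: int = 0) -> PositionProfile:
    """Per-position spread of the 16 dinucleotide frequencies.

    At each dinucleotide position the 16 observed frequencies (fraction
    units) are compared with their mean 1/16; the default is the population
    standard deviation (divide by 16), ``ddof=1`` gives the sample variant.
    A flat distribution gives 0; a position dominated by one dinucleotide
    approaches sqrt(15)/16 ≈ 0.242.
    """
    fp = frequency_profile(pset, k=2, alphabet="ACGT", units="fraction")
    dev = fp.freq - 1.0 / 16.0
    with np.errstate(invalid="ignore"):
        sd = np.sqrt(np.nansum(dev**2, axis=0) / (16 - ddof))
    sd = np.where(fp.n_eff > 0, sd, np.nan)
    return PositionProfile(
        labels=fp.labels,
        values=sd,
        n_eff=fp.n_eff,
        strand="upper",
        table_name="dinucleotide_sd",
        units="fraction",
    )


def _motif_lookup(motif: str) -> list[np.ndarray]:
    """Per-letter boolean lookup over base codes (A,C,G,T,N).

    A sequence N is matched only by motif letter N ("any base"); determinate
    motif letters never match an unknown base.
    """
    luts = []
    for ch in motif.upper():
        if ch not in IUPAC_CLASSES:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif {motif!r}")
        allowed = IUPAC_CLASSES[ch]
        lut = np.zeros(5, dtype=bool)
        for b in allowed:
            lut["ACGT".index(b)] = True
        if ch == "N":
            lut[N_CODE] = True
        luts.append(lut)
    return luts


def motif_matches(pset: PromoterSet, motif: str) -> np.ndarray:
    """(n, L − m + 1) boolean matrix: motif match at every window start."""
    m = len(motif)
    if not 1 <= m <= pset.length:
        raise ValueError(f"motif length {m} outside 1..{pset.length}")
    luts = _motif_lookup(motif)
    n_win = pset.length - m + 1
    out = np.ones((len(pset), n_win), dtype=bool)
    for i, lut in enumerate(luts):
        out &= lut[pset.codes[:, i : i + n_win]]
    return out


def motif_occurrence_profile(pset: PromoterSet, motif: str) -> PositionProfile:
    """Fraction of sequences matching an IUPAC motif at each window.

    Degenerate letters follow IUPAC semantics (W={A,T}, S={G,C}, Y={C,T},
    R={A,G}, N=any). Windows are labelled like k-mer windows of the motif's
    length (centre rule), so motif peaks line up with T-index profiles.
    """
    if len(pset) == 0:
        raise ValueError("empty promoter set")
    matches = motif_matches(pset, motif)
    return PositionProfile(
        labels=_window_labels(len(motif), pset.labels),
        values=matches.mean(axis=0),
        n_eff=np.full(matches.shape[1], len(pset)),
        strand="upper",
        table_name=f"occurrence:{motif.upper()}",
        units="fraction",
    )
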