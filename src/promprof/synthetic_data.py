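"""Synthetic TSS-aligned promoter-like sequence sets.

The generator draws fixed-length sequences from a (optionally
position-dependent) background base distribution and then plants IUPAC
motifs — typically a TATA-box-like element starting near −31 (the TBP
footprint spans roughly −34…−24 from the TSS) and a pyrimidine–purine
initiator step at (−1, +1). Every run is driven by a single explicitly
seeded pseudo-random stream: background bases for all sequences are drawn
first, then each motif in list order, so output is reproducible and stays
stable for the background part when the motif list changes.

What the generator does NOT emulate: dinucleotide-level correlation
structure of real promoters, species-fitted backgrounds, or
position-dependent motif placement jitter. Tests passing on generated sets
therefore validate the profiling machinery, not biological conclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._coding import BASES, decode_sequences
from .composition_profiles import IUPAC_CLASSES
from .seqset_io import PromoterSet, _make_labels

logger = logging.getLogger(__name__)

__all__ = ["MotifSpec", "GeneratorConfig", "generate_promoter_set", "species_like_config"]


@dataclass
class MotifSpec:
    """An IUPAC motif planted at a fixed signed position with a probability.

    Degenerate letters are resolved uniformly over their class, per
    sequence, each time the motif is planted.
    """

    pattern: str
    start_label: int
    probability: float = 1.0

    def __post_init__(self):
        self.pattern = self.pattern.upper()
        for ch in self.pattern:
            if ch not in IUPAC_CLASSES:
                raise ValueError(f"invalid IUPAC letter {ch!r} in {self.pattern!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic promoter set.

    ``background`` is either 4 global base probabilities (A, C, G, T order)
    or a 4 × length matrix of per-position probabilities; columns must sum
    to 1.
    """

    n: int
    length: int = 60
    tss_offset: int = 50
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    motifs: list[MotifSpec] = field(default_factory=list)
    seed: int = 0

    def background_matrix(self) -> np.ndarray:
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim == 1:
            if bg.shape != (4,):
                raise ValueError("global background must have 4 probabilities")
            bg = np.tile(bg[:, None], (1, self.length))
        if bg.shape != (4, self.length):
            raise ValueError(
                f"background must be 4×{self.length}, got {bg.shape}"
            )
        if (bg < 0).any() or not np.allclose(bg.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("background columns must be nonnegative and sum to 1")
        return bg


def _motif_span(spec: MotifSpec, length: int, tss_offset: int) -> tuple[int, int]:
    labels = _make_labels(length, tss_offset)
    start = spec.start_label + tss_offset if spec.start_label < 0 else (
        spec.start_label + tss_offset - 1
    )
    if spec.start_label == 0:
        raise ValueError("motif start label 0 does not exist")
    end = start + len(spec.pattern)
    if start < 0 or end > length:
        raise ValueError(
            f"motif {spec.pattern} at {spec.start_label:+d} exceeds sequence "
            f"bounds {labels[0]:+d}..{labels[-1]:+d}"
        )
    return start, end


def generate_promoter_set(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> PromoterSet:
    """Draw n i.i.d. sequences: background first, then motifs in list order.

    Overlapping motifs are resolved in list order (later specs overwrite
    earlier ones where planted); a log message records any overlap.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bg = config.background_matrix()
    n, L = config.n, config.length

    spans = [_motif_span(m, L, config.tss_offset) for m in config.motifs]
    for i in range(1, len(spans)):
        for j in range(i):
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            if lo < hi:
                logger.info(
                    "motifs %s and %s overlap at columns %d..%d; later spec wins",
                    config.motifs[j].pattern, config.motifs[i].pattern, lo, hi - 1,
                )

    # background: one uniform draw per cell, inverted through per-position CDF
    u = rng.random((n, L))
    cdf = np.cumsum(bg, axis=0)
    codes = np.empty((n, L), dtype=np.uint8)
    for j in range(L):
        codes[:, j] = np.searchsorted(cdf[:, j], u[:, j], side="right")
    np.minimum(codes, 3, out=codes)  # guard against u == 1.0 edge

    for spec, (start, end) in zip(config.motifs, spans):
        planted = rng.random(n) < spec.probability
        idx = np.flatnonzero(planted)
        for offset, ch in enumerate(spec.pattern):
            cls = IUPAC_CLASSES[ch]
            cls_codes = np.array([BASES.index(b) for b in cls], dtype=np.uint8)
            if len(cls_codes) == 1:
                codes[idx, start + offset] = cls_codes[0]
            else:
                codes[idx, start + offset] = cls_codes[
                    rng.integers(0, len(cls_codes), size=len(idx))
                ]

    return PromoterSet(decode_sequences(codes), L, config.tss_offset)


# -- presets -----------------------------------------------------------------

_PRESETS = ("mammal_like", "at_rich_like", "uniform")


def species_like_config(preset: str, n: int = 10000, seed: int = 0) -> GeneratorConfig:
    """Ready-made configs echoing broad species contrasts.

    mammal_like
        GC(S)-rich background (A/T 0.20, C/G 0.30) with a W-rich patch at
        −30…−26 where W and S are balanced; TATAWAAR planted at −31 with
        probability 0.15 (the classic consensus is found in 10–20% of
        metazoan core promoters) and a YR initiator step at (−1, +1) with
        probability 0.75.
    at_rich_like
        Globally AT(W)-rich background (A/T 0.325, C/G 0.175), TATAWAAR at
        −31 with probability 0.29, YR initiator with probability 0.75.
    uniform
        Flat 25% background, no motifs.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; one of {_PRESETS}")
    length, tss_offset = 60, 50
    if preset == "uniform":
        return GeneratorConfig(n=n, length=length, tss_offset=tss_offset, seed=seed)

    if preset == "mammal_like":
        bg = np.tile(np.array([0.20, 0.30, 0.30, 0.20])[:, None], (1, length))
        labels = _make_labels(length, tss_offset)
        patch = (labels >= -30) & (labels <= -26)
        bg[:, patch] = np.array([0.25, 0.25, 0.25, 0.25])[:, None]
        tata_p = 0.15
    else:  # at_rich_like
        bg = np.tile(np.array([0.325, 0.175, 0.175, 0.325])[:, None], (1, length))
        tata_p = 0.29
    motifs = [
        MotifSpec("TATAWAAR", start_label=-31, probability=tata_p),
        MotifSpec("YR", start_label=-1, probability=0.75),
    ]
    return GeneratorConfig(
        n=n, length=length, tss_offset=tss_offset, background=bg,
        motifs=motifs, seed=seed,
    )
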