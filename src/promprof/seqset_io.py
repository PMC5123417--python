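"""Fixed-length, TSS-aligned promoter sequence sets.

Positions are labelled relative to the transcription start site (TSS): the
TSS base is +1, upstream positions are negative, and there is no position 0.
A 60-nt set with the TSS at 0-based index 50 is labelled −50…−1, +1…+10.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._coding import encode_sequences

logger = logging.getLogger(__name__)

__all__ = ["PromoterSet", "load_promoter_set", "save_promoter_set", "merge_promoter_sets"]


def _make_labels(length: int, tss_offset: int) -> np.ndarray:
    """Signed position labels with 0 skipped; label[tss_offset] == +1."""
    idx = np.arange(length)
    return np.where(idx < tss_offset, idx - tss_offset, idx - tss_offset + 1)


class PromoterSet:
    """A set of equal-length upper-case DNA sequences aligned at the TSS.

    Parameters
    ----------
    sequences : DNA strings over ACGT (optionally N), all of ``length``.
    length : sequence length in nt (default 60).
    tss_offset : 0-based index of the +1 (TSS) position (default 50).
    ids : optional per-sequence identifiers, same order as sequences.
    """

    def __init__(
        self,
        sequences: Sequence[str],
        length: int = 60,
        tss_offset: int = 50,
        ids: Sequence[str] | None = None,
    ):
        sequences = [s.upper() for s in sequences]
        if not 0 <= tss_offset < length:
            raise ValueError(f"tss_offset {tss_offset} outside 0..{length - 1}")
        for i, seq in enumerate(sequences):
            if len(seq) != length:
                name = ids[i] if ids is not None else f"#{i}"
                raise ValueError(
                    f"sequence {name} has length {len(seq)}, expected {length}"
                )
        if ids is not None and len(ids) != len(sequences):
            raise ValueError("ids and sequences differ in length")
        self.sequences = sequences
        self.length = length
        self.tss_offset = tss_offset
        self.ids = list(ids) if ids is not None else None
        self._codes = encode_sequences(sequences) if sequences else np.zeros(
            (0, length), dtype=np.uint8
        )
        self.labels = _make_labels(length, tss_offset)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __repr__(self) -> str:
        return (
            f"PromoterSet(n={len(self)}, length={self.length}, "
            f"labels {self.labels[0]:+d}..{self.labels[-1]:+d})"
        )

    @property
    def codes(self) -> np.ndarray:
        """(n, length) uint8 base-code matrix (A..T = 0..3, N = 4)."""
        return self._codes

    # -- coordinate system ---------------------------------------------------

    def pos_to_index(self, label: int) -> int:
        """0-based column index of a signed position label (no label 0)."""
        if label == 0:
            raise ValueError("position 0 does not exist; the TSS is +1")
        idx = label + self.tss_offset if label < 0 else label + self.tss_offset - 1
        if not 0 <= idx < self.length:
            raise ValueError(
                f"label {label:+d} outside {self.labels[0]:+d}..{self.labels[-1]:+d}"
            )
        return int(idx)

    def index_to_pos(self, index: int) -> int:
        """Signed position label of a 0-based column index."""
        if not 0 <= index < self.length:
            raise ValueError(f"index {index} outside 0..{self.length - 1}")
        return int(self.labels[index])

    # -- derived sets --------------------------------------------------------

    def subset(self, keep: Iterable[int] | np.ndarray) -> "PromoterSet":
        """New set containing the selected rows (indices or boolean mask)."""
        keep = np.asarray(list(keep) if not isinstance(keep, np.ndarray) else keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        seqs = [self.sequences[i] for i in keep]
        ids = [self.ids[i] for i in keep] if self.ids is not None else None
        return PromoterSet(seqs, self.length, self.tss_offset, ids)


def merge_promoter_sets(a: PromoterSet, b: PromoterSet) -> PromoterSet:
    """Concatenate two sets sharing the same geometry."""
    if (a.length, a.tss_offset) != (b.length, b.tss_offset):
        raise ValueError("cannot merge sets with different geometry")
    ids = None
    if a.ids is not None and b.ids is not None:
        ids = a.ids + b.ids
    return PromoterSet(a.sequences + b.sequences, a.length, a.tss_offset, ids)


def load_promoter_set(
    path: str | Path,
    format: str = "fasta",
    length: int = 60,
    tss_offset: int = 50,
    strict: bool = False,
) -> PromoterSet:
    """Load a TSS-aligned promoter set from FASTA or one-sequence-per-line text.

    Records whose length differs from ``length`` are dropped with a logged
    count (``strict=True`` raises instead). Characters outside ACGTN raise,
    naming the offending record. An empty set after filtering raises.
    """
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "lines":
        with open(path) as fh:
            records = [
                (f"line{i + 1}", line.strip().upper())
                for i, line in enumerate(fh)
                if line.strip()
            ]
    else:
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'lines'")

    for name, seq in records:
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {name} contains non-IUPAC characters {sorted(bad)}"
            )

    kept = [(name, seq) for name, seq in records if len(seq) == length]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        if strict:
            raise ValueError(
                f"{n_dropped} record(s) in {path.name} have length != {length}"
            )
        logger.warning(
            "%s: dropped %d record(s) with length != %d", path.name, n_dropped, length
        )
    if not kept:
        raise ValueError(f"no usable sequences of length {length} in {path}")
    return PromoterSet(
        [seq for _, seq in kept], length, tss_offset, ids=[name for name, _ in kept]
    )


def save_promoter_set(pset: PromoterSet, path: str | Path, format: str = "fasta") -> None:
    """Write a set back out as FASTA or one-sequence-per-line text."""
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(
                Seq(seq),
                id=pset.ids[i] if pset.ids is not None else f"seq{i + 1}",
                description="",
            )
            for i, seq in enumerate(pset.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "lines":
        path.write_text("".join(s + "\n" for s in pset.sequences))
    else:
        raise ValueError(f"unknown format {format!r}")
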