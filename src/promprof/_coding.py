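"""Integer coding of DNA sequences and k-mers.

Bases A, C, G, T are coded 0–3; N is coded 4 and marks an unknown base.
A k-mer is coded as a radix-4 integer with the leftmost (5') base most
significant, so lexicographic order of words equals numeric order of codes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BASES = "ACGT"
N_CODE = 4

_CHAR_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CHAR_TO_CODE[ord(_b)] = _i
_CHAR_TO_CODE[ord("N")] = N_CODE

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode equal-length upper-case sequences into an (n, L) uint8 matrix.

    Raises ValueError (naming the offending row) on characters outside ACGTN.
    """
    n = len(sequences)
    if n == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    raw = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    codes = _CHAR_TO_CODE[raw].reshape(n, -1)
    bad = codes == 255
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValueError(
            f"sequence {row} contains a character outside ACGTN: "
            f"{sequences[row]!r}"
        )
    return codes


def decode_sequences(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer((BASES + "N").encode("ascii"), dtype=np.uint8)
    return [bytes(lut[row]).decode("ascii") for row in codes]


def kmer_code(word: str) -> int:
    """Radix-4 code of an ACGT word (no N allowed in table keys)."""
    code = 0
    for ch in word:
        i = BASES.find(ch)
        if i < 0:
            raise ValueError(f"not an ACGT word: {word!r}")
        code = code * 4 + i
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def all_kmers(k: int) -> list[str]:
    return [code_to_kmer(c, k) for c in range(4**k)]


def revcomp(word: str) -> str:
    """Watson–Crick reverse complement of a DNA word over ACGTN."""
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(word))
    except KeyError as exc:
        raise ValueError(f"not a DNA word over ACGTN: {word!r}") from exc


def revcomp_permutation(k: int) -> np.ndarray:
    """Permutation p of 0..4^k-1 with p[code(w)] == code(revcomp(w)).

    An involution: applying it twice is the identity.
    """
    codes = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(codes)
    for i in range(k):
        digit = (codes >> (2 * (k - 1 - i))) & 3
        out |= (3 - digit) << (2 * i)
    return out


def window_codes(codes: np.ndarray, k: int, mapping: np.ndarray | None = None) -> np.ndarray:
    """Radix codes of every length-k window of every sequence.

    Parameters
    ----------
    codes : (n, L) uint8 base codes (A..T = 0..3, N = 4).
    k : window length, 1 <= k <= L.
    mapping : optional length-5 array collapsing base codes into a smaller
        alphabet (e.g. purine/pyrimidine); entries for valid bases must be
        < radix, the entry for N is ignored.

    Returns
    -------
    (n, L - k + 1) int64 matrix; windows containing N are set to -1.
    """
    n, L = codes.shape
    if not 1 <= k <= L:
        raise ValueError(f"window size k={k} outside 1..{L}")
    valid = sliding_window_view(codes < N_CODE, k, axis=1).all(axis=-1)
    if mapping is not None:
        mapped = mapping[codes]
        radix = int(mapping[:N_CODE].max()) + 1
    else:
        mapped = codes
        radix = 4
    win = sliding_window_view(mapped, k, axis=1).astype(np.int64)
    weights = radix ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = win @ weights
    out[~valid] = -1
    return out
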