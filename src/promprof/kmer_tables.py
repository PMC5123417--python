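"""k-mer → value property tables with strand semantics.

Two families of tables are distinguished by ``strand_semantics``:

``duplex_step``
    Base-pair-step parameters of the double helix (stacking energy, Roll,
    Slide, stiffnesses, entropy, melting temperature). A step and its
    reverse complement describe the same duplex fragment, so the table is
    constrained to ``value(w) == value(revcomp(w))`` — 10 unique values for
    the 16 dinucleotide steps.

``per_strand``
    Single-strand indexes (ultrasonic cleavage R/T/S, DNase I hexamer
    indexes, mobility to bend). A word and its reverse complement may carry
    different values: cleavage intensity differs between complementary
    words when their base-paired fragment is asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._coding import all_kmers, code_to_kmer, kmer_code, revcomp, revcomp_permutation

__all__ = ["KmerPropertyTable", "load_kmer_table", "derive_s_table", "revcomp"]

PER_STRAND = "per_strand"
DUPLEX_STEP = "duplex_step"

# duplex-symmetry tolerance when classifying loaded tables
_SYM_ATOL = 1e-9


@dataclass
class KmerPropertyTable:
    """Complete map from all 4^k ACGT k-mers to real values.

    ``values`` is a flat array indexed by radix-4 k-mer code (A=0..T=3,
    leftmost base most significant); ``table["CA"]`` also works.
    """

    k: int
    values: np.ndarray
    name: str = ""
    units: str = ""
    strand_semantics: str = PER_STRAND

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4**self.k,):
            raise ValueError(
                f"expected {4 ** self.k} values for k={self.k}, "
                f"got shape {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"table {self.name!r} contains non-finite values")
        if self.strand_semantics not in (PER_STRAND, DUPLEX_STEP):
            raise ValueError(f"unknown strand_semantics {self.strand_semantics!r}")
        if self.strand_semantics == DUPLEX_STEP:
            perm = revcomp_permutation(self.k)
            if not np.allclose(self.values, self.values[perm], rtol=0, atol=_SYM_ATOL):
                bad = int(np.argmax(np.abs(self.values - self.values[perm])))
                raise ValueError(
                    f"duplex_step table {self.name!r} violates "
                    f"value(w)==value(revcomp(w)) at {code_to_kmer(bad, self.k)}"
                )

    def __getitem__(self, word: str) -> float:
        if len(word) != self.k:
            raise KeyError(f"word {word!r} has length {len(word)}, table k={self.k}")
        return float(self.values[kmer_code(word)])

    @property
    def lower_strand_values(self) -> np.ndarray:
        """Values looked up through the reverse complement (template strand)."""
        if self.strand_semantics == DUPLEX_STEP:
            return self.values
        return self.values[revcomp_permutation(self.k)]

    @classmethod
    def from_dict(
        cls,
        k: int,
        mapping: dict[str, float],
        name: str = "",
        units: str = "",
        strand_semantics: str = PER_STRAND,
    ) -> "KmerPropertyTable":
        missing = [w for w in all_kmers(k) if w not in mapping]
        if missing:
            shown = ", ".join(missing[:8]) + ("…" if len(missing) > 8 else "")
            raise ValueError(f"incomplete table: {len(missing)} k-mer(s) missing: {shown}")
        values = np.empty(4**k)
        for word, val in mapping.items():
            values[kmer_code(word)] = val
        return cls(k, values, name, units, strand_semantics)

    def to_dict(self) -> dict[str, float]:
        return {code_to_kmer(c, self.k): float(v) for c, v in enumerate(self.values)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.name or 'kmer table'} (k={self.k}, "
                     f"{self.strand_semantics}"
                     + (f", {self.units}" if self.units else "") + ")\n")
            for word, val in self.to_dict().items():
                fh.write(f"{word}\t{val:.10g}\n")


def _load_generic_tsv(path: Path, k: int) -> dict[str, float]:
    mapping: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 'kmer<TAB>value'")
            word, val = parts[0].upper(), float(parts[1])
            if len(word) != k:
                raise ValueError(
                    f"{path.name}:{lineno}: word {word!r} has length {len(word)}, "
                    f"expected k={k}"
                )
            if word in mapping:
                raise ValueError(f"{path.name}:{lineno}: duplicate k-mer {word}")
            mapping[word] = val
    return mapping


def _load_diprodb(path: Path, property_name: str | None) -> tuple[dict[str, float], str]:
    """One property row of a DiProDB-style export.

    Expected layout: tab-separated, a header line containing dinucleotide
    column names (at least the 10 canonical steps), then one data row per
    property; non-dinucleotide columns (ID, PropertyName, …) identify rows.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path.name}: empty DiProDB file")
    header = lines[0].split("\t")
    dinucs = all_kmers(2)
    di_cols = {col.upper(): i for i, col in enumerate(header) if col.upper() in dinucs}
    if not di_cols:
        raise ValueError(f"{path.name}: header has no dinucleotide columns")
    meta_cols = [i for i, col in enumerate(header) if col.upper() not in dinucs]

    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        key = tuple(parts[i] for i in meta_cols if i < len(parts))
        rows.append((key, parts))
    if property_name is None:
        if len(rows) != 1:
            names = ", ".join("/".join(k) for k, _ in rows)
            raise ValueError(
                f"{path.name}: several property rows ({names}); pass property="
            )
        key, parts = rows[0]
    else:
        matches = [(k, p) for k, p in rows if property_name in k]
        if not matches:
            names = ", ".join("/".join(k) for k, _ in rows)
            raise ValueError(f"property {property_name!r} not found; available: {names}")
        key, parts = matches[0]

    mapping = {w: float(parts[i]) for w, i in di_cols.items() if i < len(parts)}
    # a 10-unique-step export omits redundant columns: complete by revcomp
    for w in dinucs:
        if w not in mapping:
            rc = revcomp(w)
            if rc in mapping:
                mapping[w] = mapping[rc]
    return mapping, "/".join(k for k in key if k)


def load_kmer_table(
    path: str | Path,
    k: int = 2,
    dialect: str = "generic_tsv",
    name: str = "",
    units: str = "",
    strand_semantics: str | None = None,
    property: str | None = None,
) -> KmerPropertyTable:
    """Load a k-mer property table.

    dialect='generic_tsv': two whitespace-separated columns (k-mer, value),
    '#' comments; all 4^k words required, duplicates are an error.
    dialect='diprodb': DiProDB export with a dinucleotide-named header and
    one row per property (k is forced to 2); rows carrying only the 10
    canonical steps are completed by reverse complementation.

    ``strand_semantics`` is inferred when not given: a table symmetric under
    reverse complementation is classified ``duplex_step``.
    """
    path = Path(path)
    if dialect == "generic_tsv":
        mapping = _load_generic_tsv(path, k)
    elif dialect == "diprodb":
        k = 2
        mapping, row_name = _load_diprodb(path, property)
        name = name or row_name
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if strand_semantics is None:
        symmetric = all(
            w in mapping and revcomp(w) in mapping
            and abs(mapping[w] - mapping[revcomp(w)]) <= _SYM_ATOL
            for w in mapping
        )
        strand_semantics = DUPLEX_STEP if symmetric and mapping else PER_STRAND
    return KmerPropertyTable.from_dict(
        k, mapping, name=name or path.stem, units=units, strand_semantics=strand_semantics
    )


def derive_s_table(
    t_table: KmerPropertyTable, r_table: KmerPropertyTable
) -> KmerPropertyTable:
    """Flanking-context cleavage contribution S = T − R(centre).

    For every tetranucleotide n1n2n3n4, S is the tetranucleotide cleavage
    index minus the dinucleotide index of its central step n2n3. Negative S
    means the flanking bases n1, n4 damp cleavage at the central bond.
    """
    if t_table.k != 4 or r_table.k != 2:
        raise ValueError(
            f"expected k=4 and k=2 tables, got k={t_table.k} and k={r_table.k}"
        )
    if DUPLEX_STEP in (t_table.strand_semantics, r_table.strand_semantics):
        raise ValueError("S is defined for per_strand cleavage tables only")
    codes = np.arange(256)
    centre = (codes >> 2) & 15  # digits n2 n3 of n1 n2 n3 n4
    values = t_table.values - r_table.values[centre]
    return KmerPropertyTable(
        4,
        values,
        name=f"S({t_table.name or 'T'}-{r_table.name or 'R'})",
        units=t_table.units,
        strand_semantics=PER_STRAND,
    )
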