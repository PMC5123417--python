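import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promprof import (
    KmerPropertyTable,
    derive_s_table,
    load_kmer_table,
    revcomp,
    synthetic_ultrasonic_r_table,
    synthetic_ultrasonic_t_table,
)
from promprof._coding import all_kmers
from promprof.kmer_tables import DUPLEX_STEP, PER_STRAND

dna = st.text(alphabet="ACGTN", min_size=1, max_size=12)


class TestRevcomp:
    @pytest.mark.parametrize(
        "word,expected", [("CA", "TG"), ("ACGA", "TCGT"), ("AT", "AT"), ("NAC", "GTN")]
    )
    def test_examples(self, word, expected):
        assert revcomp(word) == expected

    @given(word=dna)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_involution(self, word):
        assert revcomp(revcomp(word)) == word

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestTableConstruction:
    def test_complete_table_from_dict(self, toy_r_table):
        assert toy_r_table.k == 2
        assert len(toy_r_table.values) == 16
        assert toy_r_table["AA"] == pytest.approx(0.5 + 0.031 * 0)

    def test_missing_kmers_named(self):
        mapping = {w: 1.0 for w in all_kmers(4)}
        del mapping["ACGT"]
        with pytest.raises(ValueError, match="ACGT"):
            KmerPropertyTable.from_dict(4, mapping)

    def test_duplex_constraint_enforced(self):
        values = {w: 1.0 for w in all_kmers(2)}
        values["GA"] = 2.0  # breaks value(GA) == value(TC)
        with pytest.raises(ValueError, match="GA|TC"):
            KmerPropertyTable.from_dict(2, values, strand_semantics=DUPLEX_STEP)

    def test_non_finite_rejected(self):
        vals = np.ones(16)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            KmerPropertyTable(2, vals)

    def test_lower_strand_values(self, toy_r_table):
        lower = toy_r_table.lower_strand_values
        for w in all_kmers(2):
            assert lower[list(all_kmers(2)).index(w)] == toy_r_table[revcomp(w)]


class TestGenericTsv:
    def test_load_16_rows(self, tmp_path, toy_r_table):
        p = tmp_path / "r.tsv"
        toy_r_table.to_tsv(p)
        back = load_kmer_table(p, k=2, strand_semantics=PER_STRAND)
        np.testing.assert_allclose(back.values, toy_r_table.values)

    def test_missing_row_error_names_kmer(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = [f"{w}\t1.0" for w in all_kmers(4) if w != "GGTA"]
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="GGTA"):
            load_kmer_table(p, k=4)

    def test_duplicate_row_error(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("\n".join(f"{w}\t1.0" for w in all_kmers(2)) + "\nAA\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_kmer_table(p, k=2)

    def test_symmetric_table_classified_duplex(self, tmp_path):
        p = tmp_path / "sym.tsv"
        p.write_text(
            "\n".join(f"{w}\t{min(w, revcomp(w))=='AA' and 2.0 or 1.0}" for w in all_kmers(2))
            + "\n"
        )
        assert load_kmer_table(p, k=2).strand_semantics == DUPLEX_STEP


class TestDiprodb:
    def _write(self, tmp_path, dinucs, values, name="Stacking energy"):
        header = "ID\tPropertyName\t" + "\t".join(dinucs)
        row = "1\t" + name + "\t" + "\t".join(str(v) for v in values)
        p = tmp_path / "diprodb.tsv"
        p.write_text(header + "\n" + row + "\n")
        return p

    def test_full_16_column_row(self, tmp_path):
        dinucs = all_kmers(2)
        values = [1.0 + 0.1 * (all_kmers(2).index(min(w, revcomp(w)))) for w in dinucs]
        p = self._write(tmp_path, dinucs, values)
        t = load_kmer_table(p, dialect="diprodb")
        assert t.k == 2
        assert t.strand_semantics == DUPLEX_STEP
        assert t["GA"] == t["TC"]

    def test_ten_step_row_completed_by_revcomp(self, tmp_path):
        """10 canonical steps expand to a revcomp-closed 16-entry table."""
        canonical = ["AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA"]
        values = [float(i) for i in range(10)]
        p = self._write(tmp_path, canonical, values)
        t = load_kmer_table(p, dialect="diprodb")
        assert t.strand_semantics == DUPLEX_STEP
        for w in all_kmers(2):
            assert t[w] == t[revcomp(w)]
        assert t["TT"] == t["AA"] == 0.0
        assert t["GT"] == t["AC"] == 1.0

    def test_property_row_selection(self, tmp_path):
        dinucs = all_kmers(2)
        header = "ID\tPropertyName\t" + "\t".join(dinucs)
        rows = [
            "1\tRoll\t" + "\t".join("1.0" for _ in dinucs),
            "2\tSlide\t" + "\t".join("2.0" for _ in dinucs),
        ]
        p = tmp_path / "multi.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        assert load_kmer_table(p, dialect="diprodb", property="Slide")["AA"] == 2.0
        with pytest.raises(ValueError, match="Roll"):
            load_kmer_table(p, dialect="diprodb")  # ambiguous → lists rows
        with pytest.raises(ValueError, match="not found"):
            load_kmer_table(p, dialect="diprodb", property="Twist")


class TestDeriveS:
    def test_definition_arithmetic(self):
        t_vals = {w: 1.5 if w == "ACGA" else 1.0 for w in all_kmers(4)}
        r_vals = {w: 1.1 if w == "CG" else 1.0 for w in all_kmers(2)}
        s = derive_s_table(
            KmerPropertyTable.from_dict(4, t_vals), KmerPropertyTable.from_dict(2, r_vals)
        )
        assert s["ACGA"] == pytest.approx(0.4)
        assert s["AAAA"] == pytest.approx(0.0)

    def test_annihilation_when_t_is_broadcast_r(self, toy_r_table):
        t_vals = {w: toy_r_table[w[1:3]] for w in all_kmers(4)}
        s = derive_s_table(KmerPropertyTable.from_dict(4, t_vals), toy_r_table)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_shift_invariance(self, toy_t_table, toy_r_table):
        """Adding a constant to both T and R leaves S unchanged."""
        s0 = derive_s_table(toy_t_table, toy_r_table)
        shifted_t = KmerPropertyTable(4, toy_t_table.values + 3.7)
        shifted_r = KmerPropertyTable(2, toy_r_table.values + 3.7)
        s1 = derive_s_table(shifted_t, shifted_r)
        np.testing.assert_allclose(s0.values, s1.values, atol=1e-12)

    def test_k_mismatch(self, toy_r_table):
        with pytest.raises(ValueError, match="k="):
            derive_s_table(toy_r_table, toy_r_table)

    def test_packaged_tables_regression(self):
        """Frozen: S(ACGA) = T(ACGA) − R(CG) on the packaged tables."""
        r = synthetic_ultrasonic_r_table()
        t = synthetic_ultrasonic_t_table()
        s = derive_s_table(t, r)
        assert s["ACGA"] == pytest.approx(t["ACGA"] - r["CG"], abs=1e-12)
        assert round(s["ACGA"], 3) == 0.417
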