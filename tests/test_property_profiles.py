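import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promprof import (
    KmerPropertyTable,
    PromoterSet,
    assign_window_labels,
    derive_s_table,
    merge_promoter_sets,
    property_profile,
    revcomp,
    strand_difference_profile,
    synthetic_duplex_step_table,
)
from promprof._coding import all_kmers

from conftest import make_uniform_set

DEFAULT_LABELS = PromoterSet(["A" * 60]).labels


def naive_profile(pset, table, strand="upper"):
    """Independent double-loop oracle: mean table value per window."""
    k = table.k
    out = []
    for j in range(pset.length - k + 1):
        total, count = 0.0, 0
        for seq in pset.sequences:
            word = seq[j : j + k]
            if "N" in word:
                continue
            if strand == "lower":
                word = revcomp(word)
            total += table[word]
            count += 1
        out.append(total / count if count else np.nan)
    return np.array(out)


class TestWindowLabels:
    @pytest.mark.parametrize(
        "k,n_labels,first,last",
        [(2, 59, -49, 10), (4, 57, -48, 9), (6, 55, -47, 8)],
    )
    def test_default_geometry_enumerations(self, k, n_labels, first, last):
        labels = assign_window_labels(k, DEFAULT_LABELS)
        assert len(labels) == n_labels
        assert labels[0] == first and labels[-1] == last
        # the window straddling the TSS bond is labelled +1
        bond_window_start = 50 - k // 2
        assert labels[bond_window_start] == 1

    def test_odd_k_has_no_central_bond(self):
        with pytest.raises(ValueError, match="odd"):
            assign_window_labels(3, DEFAULT_LABELS)

    @given(k=st.sampled_from([2, 4, 6, 8]), length=st.integers(10, 80))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_centre_rule_on_any_geometry(self, k, length):
        tss = length // 2
        labels = PromoterSet(["A" * length], length=length, tss_offset=tss).labels
        win = assign_window_labels(k, labels)
        assert len(win) == length - k + 1
        for j in range(len(win)):
            assert win[j] == labels[j + k // 2]


class TestPropertyProfile:
    def test_homopolymer_constant_per_strand(self, poly_a_set, toy_r_table):
        up = property_profile(poly_a_set, toy_r_table, "upper")
        lo = property_profile(poly_a_set, toy_r_table, "lower")
        np.testing.assert_allclose(up.values, toy_r_table["AA"], atol=1e-12)
        np.testing.assert_allclose(lo.values, toy_r_table["TT"], atol=1e-12)
        assert (up.n_eff == len(poly_a_set)).all()

    def test_duplex_table_strand_independent(self, random_set):
        table = synthetic_duplex_step_table()
        up = property_profile(random_set, table, "upper")
        lo = property_profile(random_set, table, "lower")
        np.testing.assert_array_equal(up.values, lo.values)
        diff = strand_difference_profile(random_set, table)
        np.testing.assert_array_equal(diff.values, 0.0)

    @pytest.mark.parametrize("strand", ["upper", "lower"])
    @pytest.mark.parametrize("k", [2, 4])
    def test_oracle_equivalence(self, random_set, toy_r_table, toy_t_table, strand, k):
        """Vectorized profile equals the naive double loop to 1e-12."""
        table = toy_r_table if k == 2 else toy_t_table
        prof = property_profile(random_set, table, strand)
        np.testing.assert_allclose(
            prof.values, naive_profile(random_set, table, strand), atol=1e-12
        )

    def test_oracle_equivalence_with_n_bases(self, toy_r_table, rng):
        seqs = []
        for _ in range(20):
            chars = rng.choice(list("ACGTN"), size=60, p=[0.23] * 4 + [0.08])
            seqs.append("".join(chars))
        pset = PromoterSet(seqs)
        prof = property_profile(pset, toy_r_table)
        expected = naive_profile(pset, toy_r_table)
        np.testing.assert_allclose(prof.values, expected, atol=1e-12)

    def test_all_n_column_is_missing_not_zero(self, toy_r_table, tmp_path):
        pset = PromoterSet(["NN" + "A" * 58] * 3)
        prof = property_profile(pset, toy_r_table)
        assert np.isnan(prof.values[0])
        assert prof.n_eff[0] == 0
        out = tmp_path / "prof.tsv"
        prof.to_tsv(out)
        first_data_row = out.read_text().splitlines()[1]
        assert "NA" in first_data_row

    def test_linearity_in_the_table(self, random_set, toy_r_table, rng):
        other = KmerPropertyTable(2, rng.uniform(-1, 1, 16))
        combo = KmerPropertyTable(2, 2.5 * toy_r_table.values - 0.7 * other.values)
        p = property_profile(random_set, combo)
        p1 = property_profile(random_set, toy_r_table)
        p2 = property_profile(random_set, other)
        np.testing.assert_allclose(p.values, 2.5 * p1.values - 0.7 * p2.values, atol=1e-9)

    def test_s_profile_identity(self, random_set, toy_t_table, toy_r_table):
        """profile(S) == profile(T) − profile(R) exactly on shared labels:
        the centre dinucleotide of the tetra window labelled p is the di
        window labelled p."""
        s_table = derive_s_table(toy_t_table, toy_r_table)
        ps = property_profile(random_set, s_table)
        pt = property_profile(random_set, toy_t_table)
        pr = property_profile(random_set, toy_r_table)
        shared = np.isin(pr.labels, pt.labels)
        np.testing.assert_allclose(
            ps.values, pt.values - pr.values[shared], atol=1e-12
        )

    def test_merge_weighted_mean(self, toy_r_table):
        a = make_uniform_set(30, seed=1)
        b = make_uniform_set(70, seed=2)
        pa = property_profile(a, toy_r_table)
        pb = property_profile(b, toy_r_table)
        pm = property_profile(merge_promoter_sets(a, b), toy_r_table)
        np.testing.assert_allclose(
            pm.values, (30 * pa.values + 70 * pb.values) / 100, atol=1e-9
        )

    def test_empty_set_rejected(self, toy_r_table):
        with pytest.raises(ValueError, match="empty"):
            property_profile(PromoterSet([], length=60), toy_r_table)


class TestStrandDifference:
    def test_homopolymer_difference(self, poly_a_set, toy_r_table):
        diff = strand_difference_profile(poly_a_set, toy_r_table)
        np.testing.assert_allclose(
            diff.values, toy_r_table["AA"] - toy_r_table["TT"], atol=1e-12
        )
        assert diff.strand == "difference"

    def test_revcomp_closed_set_antisymmetry(self, toy_r_table):
        """A set closed under reverse complementation has an antisymmetric
        difference profile under window mirroring."""
        base = make_uniform_set(40, seed=9)
        closed = PromoterSet(
            base.sequences + [revcomp(s) for s in base.sequences]
        )
        diff = strand_difference_profile(closed, toy_r_table)
        np.testing.assert_allclose(diff.values, -diff.values[::-1], atol=1e-12)
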