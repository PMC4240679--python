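import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import brute_force_segmentation
from rodeo.io import CountTable, RodeoParams, ValidationError
from rodeo.phi import (assignment_probabilities, average_phi, estimate_phi,
                       least_squares_segmentation, resample_reads, segment_bins)


class TestAssignmentProbabilities:
    def test_proportional_to_counts(self):
        np.testing.assert_allclose(assignment_probabilities([3, 7, 15]),
                                   np.array([3, 7, 15]) / 25.0)

    def test_zero_count_genes_get_zero_probability(self):
        np.testing.assert_allclose(assignment_probabilities([0, 1, 1]), [0, 0.5, 0.5])
        np.testing.assert_allclose(assignment_probabilities([0, 9]), [0, 1])

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            assignment_probabilities([0, 0, 0])


class TestResampleReads:
    def test_degenerate_point_mass(self):
        rng = np.random.default_rng(0)
        ac = resample_reads([0.0, 1.0], 100, rng)
        assert ac.assigned.tolist() == [0, 100]

    def test_reads_conserved_and_reproducible(self):
        p = assignment_probabilities([5, 10, 85])
        a1 = resample_reads(p, 1234, np.random.default_rng(42)).assigned
        a2 = resample_reads(p, 1234, np.random.default_rng(42)).assigned
        assert a1.sum() == 1234
        assert (a1 == a2).all()

    def test_follows_multinomial_law(self):
        # Monte-Carlo against the multinomial distribution itself
        rng = np.random.default_rng(2024)
        draws = np.array([resample_reads([0.25, 0.75], 400, rng).assigned
                          for _ in range(10_000)])
        mean = draws.mean(axis=0)
        se = np.sqrt(400 * 0.25 * 0.75 / 10_000)
        assert abs(mean[0] - 100) < 3 * se and abs(mean[1] - 300) < 3 * se
        totals = draws.sum(axis=0)
        chi2 = stats.chisquare(totals, f_exp=np.array([0.25, 0.75]) * totals.sum())
        assert chi2.pvalue > 0.001


class TestSegmentation:
    def test_hand_worked_two_segment_split(self):
        # cumulative [100, 150, 160, 161]: both segments fit exactly after pos 1
        bks, err = least_squares_segmentation(np.cumsum([100.0, 50, 10, 1]), 2)
        assert bks == [1] and err == pytest.approx(0.0, abs=1e-9)
        bins = segment_bins(np.array([100, 50, 10, 1]), 3)
        assert bins.tolist() == [3, 3, 2, 2]

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(3, 13))
            k = int(rng.integers(2, min(4, n) + 1))
            y = np.cumsum(rng.integers(1, 50, size=n).astype(float))
            bks, err = least_squares_segmentation(y, k)
            obks, oerr = brute_force_segmentation(y, k)
            assert err == pytest.approx(oerr, rel=1e-7, abs=1e-7)
            assert bks == obks

    def test_single_expressed_gene_rules(self):
        bins = segment_bins(np.array([0, 40, 0, 0]), 5)
        assert bins.tolist() == [1, 5, 1, 1]

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 500, size=200)
        b1 = segment_bins(a, 8)
        b2 = segment_bins(a * 10, 8)
        assert (b1 == b2).all()

    def test_equal_counts_share_a_bin(self):
        a = np.array([9, 9, 9, 9, 1, 1])
        bins = segment_bins(a, 4)
        assert len(set(bins[:4])) == 1 and len(set(bins[4:])) == 1

    def test_collapse_warns_when_too_few_genes(self):
        with pytest.warns(RuntimeWarning):
            bins = segment_bins(np.array([50, 10, 0, 0]), 5)
        assert bins.tolist() == [5, 4, 1, 1]

    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=60),
           st.integers(2, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_counts(self, counts, P):
        a = np.array(counts)
        if (a > 0).sum() == 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bins = segment_bins(a, P)
        order = np.argsort(-a, kind="stable")
        sb, sa = bins[order], a[order]
        assert (np.diff(sb) <= 0).all()
        for i in range(len(sa) - 1):
            if sa[i] == sa[i + 1]:
                assert sb[i] == sb[i + 1]
        assert (bins[a == 0] == 1).all()


class TestEstimatePhi:
    def test_zero_count_gene_pinned_to_bin_one(self, small_table, quick_params):
        phi = estimate_phi(small_table, "ctrl", quick_params)
        g = small_table.gene_ids.index("gD")
        assert phi.histogram[g, 0] == 1.0
        assert (phi.bin_matrix[g] == 1).all()

    def test_rows_sum_to_one(self, small_table, quick_params):
        phi = estimate_phi(small_table, "ctrl", quick_params)
        np.testing.assert_allclose(phi.histogram.sum(axis=1), 1.0, atol=1e-9)

    def test_dominant_gene_sits_in_top_bin(self):
        counts = np.array([[100_000], [50], [40], [30], [20], [10]])
        t = CountTable([f"g{i}" for i in range(6)], ["s"], counts)
        phi = estimate_phi(t, "s", RodeoParams(P=4, I=100, seed=1, mode_threshold=3))
        assert phi.histogram[0, -1] >= 0.99

    def test_equal_count_genes_have_matching_histograms(self):
        t = CountTable(["g1", "g2", "g3"], ["s"],
                       np.array([[500], [500], [100]]))
        phi = estimate_phi(t, "s", RodeoParams(P=4, I=1000, seed=2, mode_threshold=3))
        tv = 0.5 * np.abs(phi.histogram[0] - phi.histogram[1]).sum()
        assert tv < 0.1

    def test_reproducible_from_seed(self, small_table, quick_params):
        p1 = estimate_phi(small_table, "stress", quick_params)
        p2 = estimate_phi(small_table, "stress", quick_params)
        assert (p1.bin_matrix == p2.bin_matrix).all()
        assert (p1.histogram == p2.histogram).all()


class TestAveragePhi:
    def test_single_replicate_is_identity(self, small_table, quick_params):
        phi = estimate_phi(small_table, "ctrl", quick_params)
        assert average_phi([phi]) is phi

    def test_two_point_masses_average_to_half_half(self, small_table, quick_params):
        p1 = estimate_phi(small_table, "ctrl", quick_params)
        p2 = estimate_phi(small_table, "stress", quick_params)
        avg = average_phi([p1, p2])
        np.testing.assert_allclose(
            avg.histogram, (p1.histogram + p2.histogram) / 2)
        np.testing.assert_allclose(avg.histogram.sum(axis=1), 1.0, atol=1e-9)
        assert avg.averaged and avg.bin_matrix.shape[1] == 2 * quick_params.I

    def test_mismatched_gene_sets_rejected(self, small_table, quick_params):
        phi = estimate_phi(small_table, "ctrl", quick_params)
        other = estimate_phi(small_table, "stress", quick_params)
        other.gene_ids = list(other.gene_ids[::-1])
        with pytest.raises(ValidationError):
            average_phi([phi, other])
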