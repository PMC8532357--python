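"""Median tables, difference rankings, PCA/cos2 and clustergrams."""

import numpy as np
import pytest

from vinoflux import compare
from vinoflux.compare import (
    MedianTable,
    cluster_strains,
    histogram_report,
    pca_with_cos2,
    rank_absolute_median_difference,
    rank_percent_median_difference,
    reaction_medians,
)
from vinoflux.sampling import SampleSet


def table(strains, reaction_ids, medians):
    return MedianTable(strains, reaction_ids, np.asarray(medians, dtype=float))


class TestMedians:
    def test_column_medians(self):
        sets = [
            SampleSet("A", 0.0, np.array([[1.0, 5], [2, 5], [3, 5]]), ["r1", "r2"]),
            SampleSet("B", 0.0, np.array([[4.0, 7], [6, 7]]), ["r1", "r2"]),
        ]
        mt = reaction_medians(sets)
        assert mt.row("A") == pytest.approx([2.0, 5.0])
        assert mt.row("B") == pytest.approx([5.0, 7.0])

    def test_mismatched_reactions_rejected(self):
        sets = [
            SampleSet("A", 0.0, np.zeros((2, 2)), ["r1", "r2"]),
            SampleSet("B", 0.0, np.zeros((2, 2)), ["r1", "r3"]),
        ]
        with pytest.raises(ValueError, match="share reaction ids"):
            reaction_medians(sets)

    def test_chain_achr_median_near_five(self, chain_samples_10k):
        j = chain_samples_10k.reaction_ids.index("R1")
        assert np.median(chain_samples_10k.samples[:, j]) == pytest.approx(5.0, abs=0.2)


class TestAbsoluteRanking:
    def test_spread_is_range_of_medians(self):
        mt = table(["A", "B"], ["r1", "r2"], [[2, 5], [2, 1]])
        rk = rank_absolute_median_difference(mt, k=1)
        assert rk.reaction_ids() == ["r2"]
        assert rk.entries[0].spread == pytest.approx(4.0)
        assert rk.entries[0].medians == {"A": 5.0, "B": 1.0}

    def test_ties_break_lexicographically(self):
        mt = table(["A", "B"], ["r_b", "r_a", "r_c"], [[1, 1, 1], [1, 1, 1]])
        rk = rank_absolute_median_difference(mt, k=2)
        assert rk.reaction_ids() == ["r_a", "r_b"]
        assert all(e.spread == 0 for e in rk.entries)

    def test_full_k_is_permutation(self):
        rng = np.random.default_rng(0)
        ids = [f"r{i}" for i in range(10)]
        mt = table(["A", "B", "C"], ids, rng.normal(size=(3, 10)))
        rk = rank_absolute_median_difference(mt, k=10)
        assert sorted(rk.reaction_ids()) == sorted(ids)

    def test_invariant_to_common_shift(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(3, 6))
        ids = [f"r{i}" for i in range(6)]
        a = rank_absolute_median_difference(table(["A", "B", "C"], ids, M), k=6)
        b = rank_absolute_median_difference(table(["A", "B", "C"], ids, M + 7.5), k=6)
        assert a.reaction_ids() == b.reaction_ids()
        assert [e.spread for e in a.entries] == pytest.approx([e.spread for e in b.entries])

    def test_needs_two_strains(self):
        with pytest.raises(ValueError):
            rank_absolute_median_difference(table(["A"], ["r"], [[1.0]]), k=1)


class TestPercentRanking:
    def test_miniscule_fluxes_excluded(self):
        mt = table(["A", "B"], ["tiny", "real"], [[1e-14, 1.0], [3e-14, 2.0]])
        rk = rank_percent_median_difference(mt, k=5)
        assert rk.reaction_ids() == ["real"]

    def test_percent_spread_relative_to_grand_median(self):
        mt = table(["A", "B"], ["r"], [[1.0], [2.0]])
        rk = rank_percent_median_difference(mt, k=1)
        assert rk.entries[0].spread == pytest.approx(100 * 1.0 / 1.5)

    def test_zero_spread_is_zero_percent(self):
        mt = table(["A", "B"], ["r"], [[2.0], [2.0]])
        rk = rank_percent_median_difference(mt, k=1)
        assert rk.entries[0].spread == 0.0


class TestPCA:
    def low_rank_data(self):
        rng = np.random.default_rng(3)
        n_obs, n_var = 12, 8
        factors = rng.normal(size=(n_obs, 2))
        load = rng.normal(size=(2, n_var))
        return factors @ load + 1e-4 * rng.normal(size=(n_obs, n_var))

    def test_cos2_of_variables_sums_to_one(self):
        X = self.low_rank_data()
        res = pca_with_cos2(X, scale=True)
        assert res.cos2_variables.sum(axis=1) == pytest.approx(np.ones(X.shape[1]), abs=1e-9)
        assert np.all(res.cos2_variables >= 0) and np.all(res.cos2_variables <= 1 + 1e-12)

    def test_variance_fractions_sum_to_one_nonincreasing(self):
        res = pca_with_cos2(self.low_rank_data(), scale=True)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)
        assert np.all(res.variance_explained >= 0)

    def test_two_latent_factors_dominate(self):
        res = pca_with_cos2(self.low_rank_data(), scale=True)
        assert res.variance_explained[:2].sum() > 0.95

    def test_identical_observations_have_zero_score_distance(self):
        X = np.vstack([self.low_rank_data(), self.low_rank_data()[:1]])
        res = pca_with_cos2(X, scale=True)
        assert res.scores[0] == pytest.approx(res.scores[-1], abs=1e-8)

    def test_constant_variable_rejected_when_scaling(self):
        X = self.low_rank_data()
        X[:, 3] = 2.0
        with pytest.raises(ValueError, match="v3"):
            pca_with_cos2(X, scale=True)

    def test_matches_sklearn_decomposition(self):
        """Scores and explained variance agree with an independent PCA."""
        from sklearn.decomposition import PCA

        X = self.low_rank_data()
        res = pca_with_cos2(X, scale=False)
        sk = PCA(n_components=res.scores.shape[1]).fit(X)
        assert res.variance_explained == pytest.approx(sk.explained_variance_ratio_, abs=1e-9)
        # per-component sign is arbitrary; compare magnitudes
        assert np.abs(res.scores) == pytest.approx(np.abs(sk.transform(X)), abs=1e-8)

    def test_rejects_missing_values(self):
        X = self.low_rank_data()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_with_cos2(X)


class TestClustering:
    def test_proportional_strains_merge_at_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        mt = table(["A", "B", "C"], list("wxyz"), [base, 2 * base, [4, 1, 5, 2]])
        res = cluster_strains(mt)
        assert res.correlation[0, 1] == pytest.approx(1.0)
        assert res.first_merge() == ("A", "B")
        assert res.merge_tree[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_two_strains_single_merge(self):
        mt = table(["A", "B"], list("xyz"), [[1, 2, 3], [3, 1, 2]])
        res = cluster_strains(mt)
        assert len(res.merge_tree) == 1
        assert res.correlation.shape == (2, 2)
        assert res.correlation == pytest.approx(res.correlation.T)
        assert np.diag(res.correlation) == pytest.approx([1, 1])

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(4, 9))
        mt1 = table(list("ABCD"), [f"r{i}" for i in range(9)], M)
        M2 = M.copy()
        M2[2] *= 13.7
        mt2 = table(list("ABCD"), [f"r{i}" for i in range(9)], M2)
        a, b = cluster_strains(mt1), cluster_strains(mt2)
        assert a.correlation == pytest.approx(b.correlation)
        assert a.merge_tree == b.merge_tree

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(6)
        mt = table(list("ABCDE"), [f"r{i}" for i in range(12)], rng.normal(size=(5, 12)))
        res = cluster_strains(mt)
        heights = [h for _, _, h in res.merge_tree]
        assert heights == sorted(heights)

    def test_newick_is_parseable_with_all_leaves(self):
        import skbio

        rng = np.random.default_rng(7)
        mt = table(list("ABCD"), [f"r{i}" for i in range(6)], rng.normal(size=(4, 6)))
        res = cluster_strains(mt)
        tree = skbio.TreeNode.read([res.to_newick()])
        assert {t.name for t in tree.tips()} == set("ABCD")

    def test_subset_selection(self):
        mt = table(["A", "B"], ["r1", "r2", "r3"], [[1, 9, 2], [2, 1, 4]])
        res = cluster_strains(mt, subset=["r1", "r3"])
        # r1 and r3 are proportional between strains -> perfect correlation
        assert res.correlation[0, 1] == pytest.approx(1.0)
        with pytest.raises(KeyError):
            cluster_strains(mt, subset=["nope", "r1"])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_strains(mt, subset=["r1"])


class TestHistograms:
    def test_frequencies_normalised_shared_range(self):
        sets = [
            SampleSet("A", 0.0, np.array([[0.0], [1], [2], [3]]), ["r"]),
            SampleSet("B", 0.0, np.array([[5.0], [6], [7], [8]]), ["r"]),
        ]
        df = histogram_report(sets, ["r"], bins=4)
        for strain in ("A", "B"):
            sub = df[df.strain == strain]
            assert sub.frequency.sum() == pytest.approx(1.0, abs=1e-12)
        # shared range across strains
        assert df.bin_left.min() == pytest.approx(0.0)
        assert df.bin_right.max() == pytest.approx(8.0)

    def test_fixed_reaction_single_occupied_bin(self):
        sets = [SampleSet("A", 0.0, np.full((20, 1), 3.3), ["r"])]
        df = histogram_report(sets, ["r"], bins=10)
        assert (df.frequency > 0).sum() == 1

    def test_uniform_marginal_is_near_flat(self, chain_samples_10k):
        df = histogram_report([chain_samples_10k], ["R1"], bins=10)
        occupied = df[df.frequency > 0].frequency
        assert occupied.max() / occupied.min() < 1.5
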