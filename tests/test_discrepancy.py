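import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from lsirm.alignment import posterior_summary
from lsirm.data import SyndromeMap
from lsirm.discrepancy import (
    DistanceDistribution,
    UndefinedDensityError,
    beta_compare,
    cluster_respondents,
    cosine_similarity,
    distance_samples,
    kl_distance_divergence,
    ks_compare,
    overlap_R,
    overlap_heatmap,
    rank_discrepant_pairs,
    respondent_syndrome_distances,
    syndrome_centroids,
    syndrome_similarity_matrices,
)

from conftest import make_chain, make_fitted_from_params


def gaussian_overlap_oracle(mu_shift: float) -> float:
    """Numeric integral of min(phi(x), phi(x - shift)); equals 2*Phi(-shift/2)."""
    val, _ = quad(lambda x: min(norm.pdf(x), norm.pdf(x - mu_shift)), -10, 10 + mu_shift)
    return val


def dd(samples, pair=(0, 1), tag="a"):
    return DistanceDistribution(pair, np.asarray(samples, float), tag)


class TestBetaCompare:
    def test_identical_fits(self):
        fit = posterior_summary(make_chain(np.random.default_rng(0), n_items=10))
        res = beta_compare(fit, fit)
        assert res.pearson_r == pytest.approx(1.0)
        assert not res.flagged.any()

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(1)
        fit_a = posterior_summary(make_chain(rng, n_items=10))
        fit_b = posterior_summary(make_chain(np.random.default_rng(1), n_items=10))
        fit_b.beta_mean = 2.0 * fit_a.beta_mean
        res = beta_compare(fit_a, fit_b)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert not res.flagged.any()

    def test_injected_offset_items_flagged(self):
        rng = np.random.default_rng(2)
        beta_a = rng.standard_normal(40)
        noise = 0.05 * rng.standard_normal(40)
        beta_b = beta_a + noise
        beta_b[[3, 17, 28]] += 1.5
        fit_a = posterior_summary(make_chain(rng, n_items=40))
        fit_b = posterior_summary(make_chain(rng, n_items=40))
        fit_a.beta_mean = beta_a
        fit_b.beta_mean = beta_b
        res = beta_compare(fit_a, fit_b)
        flagged = set(np.flatnonzero(res.flagged))
        assert flagged >= {3, 17, 28}       # all injected offsets found
        assert len(flagged - {3, 17, 28}) <= 1  # at most one chance flag

    def test_too_few_items(self):
        fit = make_fitted_from_params([0.0, 1.0], [0.0], np.zeros((2, 2)), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            beta_compare(fit, fit)


class TestDistanceSamples:
    def test_loop_oracle(self):
        rng = np.random.default_rng(3)
        fit = posterior_summary(make_chain(rng, n_draws=30))
        d = distance_samples(fit, 1, 4)
        expected = [
            math.dist(fit.chain.W[s, 1], fit.chain.W[s, 4]) for s in range(30)
        ]
        np.testing.assert_allclose(d.samples, expected, atol=1e-12)

    def test_same_item_warns_and_zero(self):
        fit = posterior_summary(make_chain(np.random.default_rng(4)))
        with pytest.warns(RuntimeWarning):
            d = distance_samples(fit, 2, 2)
        assert (d.samples == 0).all()

    def test_constant_chain_constant_samples(self):
        rng = np.random.default_rng(5)
        chain = make_chain(rng, n_draws=8, spread=0.0)
        fit = posterior_summary(chain, align=False)
        d = distance_samples(fit, 0, 1)
        assert np.ptp(d.samples) < 1e-12


class TestOverlapR:
    def test_identical_samples_near_one(self):
        x = np.random.default_rng(6).normal(2.0, 0.5, size=2000)
        res = overlap_R(dd(x), dd(x, tag="b"))
        assert res.R >= 0.98
        assert not res.flag_different

    def test_disjoint_supports_near_zero(self):
        rng = np.random.default_rng(7)
        res = overlap_R(
            dd(rng.normal(0.5, 0.05, 1000)), dd(rng.normal(10.0, 0.05, 1000))
        )
        assert res.R < 0.01
        assert res.flag_different

    def test_gaussian_shift_matches_closed_form(self):
        rng = np.random.default_rng(8)
        xa = rng.normal(5.0, 1.0, 5000)
        xb = rng.normal(6.0, 1.0, 5000)
        res = overlap_R(dd(xa), dd(xb))
        assert res.R == pytest.approx(gaussian_overlap_oracle(1.0), abs=0.03)
        assert gaussian_overlap_oracle(1.0) == pytest.approx(2 * norm.cdf(-0.5), abs=1e-6)

    def test_monotone_decreasing_in_shift(self):
        rng = np.random.default_rng(9)
        base = rng.normal(6.0, 1.0, 3000)
        rs = [
            overlap_R(dd(base), dd(base + shift, tag="b")).R
            for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(10)
        xa, xb = rng.normal(5, 1, 800), rng.normal(5.7, 1.3, 800)
        assert overlap_R(dd(xa), dd(xb)).R == pytest.approx(
            overlap_R(dd(xb), dd(xa)).R, abs=1e-12
        )

    def test_degenerate_samples_raise(self):
        with pytest.raises(UndefinedDensityError):
            overlap_R(dd(np.zeros(100)), dd(np.zeros(100)))


class TestKLDivergence:
    def test_identical_near_zero(self):
        x = np.random.default_rng(11).normal(3.0, 0.4, 3000)
        res = kl_distance_divergence(dd(x), dd(x, tag="b"))
        assert res.kl_ab < 0.02
        assert res.symmetric < 0.02

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            xa = rng.normal(rng.uniform(8, 10), rng.uniform(0.5, 2), 500)
            xb = rng.normal(rng.uniform(8, 10), rng.uniform(0.5, 2), 500)
            res = kl_distance_divergence(dd(xa), dd(xb))
            assert res.kl_ab >= 0 and res.kl_ba >= 0

    def test_gaussian_unit_shift_matches_closed_form(self):
        # KL(N(0,1) || N(1,1)) = 1/2
        rng = np.random.default_rng(13)
        res = kl_distance_divergence(
            dd(rng.normal(6, 1, 5000)), dd(rng.normal(7, 1, 5000))
        )
        assert res.kl_ab == pytest.approx(0.5, abs=0.1)


class TestKSCompare:
    def test_identical_statistic_zero(self):
        x = np.arange(10.0)
        stat, _ = ks_compare(dd(x), dd(x, tag="b"))
        assert stat == 0.0

    def test_disjoint_statistic_one(self):
        stat, p = ks_compare(dd([1.0, 2.0, 3.0]), dd([4.0, 5.0, 6.0]))
        assert stat == 1.0
        assert 0.0 <= p <= 1.0


class TestOverlapHeatmap:
    def test_identical_fits_nothing_flagged(self):
        fit = posterior_summary(make_chain(np.random.default_rng(14), n_draws=120))
        heat = overlap_heatmap(fit, fit)
        assert heat.flagged_proportion == 0.0
        iu = np.triu_indices(fit.n_items, k=1)
        assert (heat.R[iu] > 0.95).all()

    def test_symmetric_with_nan_diagonal(self):
        rng = np.random.default_rng(15)
        fit_a = posterior_summary(make_chain(rng, n_draws=80))
        fit_b = posterior_summary(make_chain(np.random.default_rng(16), n_draws=80))
        heat = overlap_heatmap(fit_a, fit_b)
        np.testing.assert_allclose(heat.R, heat.R.T, equal_nan=True)
        assert np.isnan(np.diag(heat.R)).all()

    def test_rank_table_contains_top_pairs(self):
        rng = np.random.default_rng(17)
        fit_a = posterior_summary(make_chain(rng, n_draws=60))
        fit_b = posterior_summary(make_chain(np.random.default_rng(18), n_draws=60))
        heat = overlap_heatmap(fit_a, fit_b)
        table = rank_discrepant_pairs(fit_a, fit_b, heat, top_k=3)
        assert (table["rank_by_R"] <= 3).sum() == 3
        assert (table["rank_by_map_diff"] <= 3).sum() == 3


class TestSyndromeGeometry:
    def syn(self):
        return SyndromeMap({"0": "AB", "1": "AB", "2": "WD", "3": "none"})

    def fitted(self):
        beta = np.zeros(4)
        theta = np.zeros(3)
        W = np.array([[1.0, 0.0], [3.0, 0.0], [0.0, 2.0], [5.0, 5.0]])
        Z = np.array([[2.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        return make_fitted_from_params(beta, theta, W, Z)

    def test_centroids(self):
        fit = self.fitted()
        with pytest.warns(RuntimeWarning):  # six labels have no members
            cents = syndrome_centroids(fit, self.syn())
        np.testing.assert_allclose(cents["AB"], [2.0, 0.0])
        np.testing.assert_allclose(cents["WD"], [0.0, 2.0])
        assert "none" not in cents
        assert set(cents) == {"AB", "WD"}

    def test_single_item_syndrome_is_item_position(self):
        fit = self.fitted()
        syn = SyndromeMap({"0": "AB", "1": "none", "2": "none", "3": "none"})
        with pytest.warns(RuntimeWarning):
            cents = syndrome_centroids(fit, syn)
        np.testing.assert_allclose(cents["AB"], fit.W_mean[0])

    def test_opposite_items_centroid_origin(self):
        W = np.array([[1.0, 1.0], [-1.0, -1.0], [0.5, 0.0]])
        fit = make_fitted_from_params(np.zeros(3), np.zeros(2), W, np.zeros((2, 2)))
        syn = SyndromeMap({"0": "AB", "1": "AB", "2": "none"})
        with pytest.warns(RuntimeWarning):
            cents = syndrome_centroids(fit, syn)
        np.testing.assert_allclose(cents["AB"], [0.0, 0.0], atol=1e-12)

    def test_cosine_similarity_values(self):
        assert cosine_similarity([1, 0], [1, 0]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [-1, 0]) == pytest.approx(-1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(1 / math.sqrt(2))
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_similarity_matrices_symmetric_unit_diagonal(self):
        fit = self.fitted()
        with pytest.warns(RuntimeWarning):
            ma, mb = syndrome_similarity_matrices(fit, fit, self.syn())
        for m in (ma, mb):
            np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
            np.testing.assert_allclose(np.diag(m.to_numpy()), 1.0)

    def test_respondent_distances_loop_oracle(self):
        fit = self.fitted()
        with pytest.warns(RuntimeWarning):
            cents = syndrome_centroids(fit, self.syn())
        dist = respondent_syndrome_distances(fit, cents)
        for k in range(3):
            for s, label in enumerate(dist.columns):
                expected = math.dist(fit.Z_mean[k], cents[label])
                assert dist.iloc[k, s] == pytest.approx(expected, abs=1e-12)
        assert (dist.to_numpy() >= 0).all()

    def test_respondent_at_centroid_distance_zero(self):
        fit = self.fitted()
        with pytest.warns(RuntimeWarning):
            cents = syndrome_centroids(fit, self.syn())
        dist = respondent_syndrome_distances(fit, cents)
        assert dist.loc[dist.index[0], "AB"] == pytest.approx(0.0)  # Z[0] = (2,0)


class TestClusterRespondents:
    def test_separable_blobs(self):
        rng = np.random.default_rng(19)
        X = np.vstack(
            [rng.normal(0, 0.05, (30, 3)), rng.normal(5, 0.05, (30, 3))]
        )
        res = cluster_respondents(X, k=2, seed=0)
        assert adjusted_rand_score(np.repeat([0, 1], 30), res.labels) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(20)
        X = rng.random((50, 4))
        r1 = cluster_respondents(X, k=4, seed=5)
        r2 = cluster_respondents(X, k=4, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            cluster_respondents(np.random.default_rng(0).random((5, 2)), k=6)
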