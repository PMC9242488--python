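import math

import numpy as np
import pytest

from lsirm.alignment import (
    RigidTransform,
    match_maps,
    posterior_summary,
    procrustes_align_chain,
    procrustes_fit,
)
from lsirm.model import log_likelihood

from conftest import make_chain


def random_rigid(rng, d=2, reflect=False):
    ang = rng.uniform(0, 2 * math.pi)
    R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    if reflect:
        R = R @ np.diag([1.0, -1.0])
    return RigidTransform(R, rng.standard_normal(d))


def grid_search_residual(Z, Z0, step_deg=1.0):
    """Brute-force rigid fit over a rotation-angle grid and both reflections."""
    best = np.inf
    for reflect in (False, True):
        for ang in np.arange(0.0, 360.0, step_deg):
            a = math.radians(ang)
            R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
            if reflect:
                R = R @ np.diag([1.0, -1.0])
            rotated = Z @ R
            t = Z0.mean(axis=0) - rotated.mean(axis=0)
            best = min(best, float(np.sum((Z0 - rotated - t) ** 2)))
    return best


class TestProcrustesFit:
    def test_identity_on_equal_configs(self):
        Z = np.random.default_rng(0).standard_normal((5, 2))
        transform, residual = procrustes_fit(Z, Z)
        assert residual < 1e-16
        np.testing.assert_allclose(transform.rotation, np.eye(2), atol=1e-8)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-8)

    @pytest.mark.parametrize("reflect", [False, True])
    def test_exact_recovery_of_rigid_motion(self, reflect):
        rng = np.random.default_rng(1)
        Z0 = rng.standard_normal((7, 2))
        motion = random_rigid(rng, reflect=reflect)
        Z = motion.apply(Z0)
        _, residual = procrustes_fit(Z, Z0)
        assert residual < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_beats_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((6, 2))
        Z0 = rng.standard_normal((6, 2))
        _, residual = procrustes_fit(Z, Z0)
        assert residual <= grid_search_residual(Z, Z0) + 1e-8

    def test_residual_symmetry(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((8, 2))
        Z0 = rng.standard_normal((8, 2))
        _, r1 = procrustes_fit(Z, Z0)
        _, r2 = procrustes_fit(Z0, Z)
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_rank_deficient_warns(self):
        Z = np.zeros((4, 2))
        Z0 = np.zeros((4, 2))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            procrustes_fit(Z, Z0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            procrustes_fit(np.zeros((3, 2)), np.zeros((4, 2)))


class TestChainAlignment:
    def test_rigid_motion_chain_collapses(self):
        rng = np.random.default_rng(5)
        chain = make_chain(rng, n_draws=10, spread=0.0)
        # scatter the draws by random rigid motions of the shared configuration
        for s in range(10):
            motion = random_rigid(rng, reflect=bool(s % 2))
            chain.W[s] = motion.apply(chain.W[s])
            chain.Z[s] = motion.apply(chain.Z[s])
        aligned = procrustes_align_chain(chain)
        for s in range(10):
            np.testing.assert_allclose(aligned.W[s], aligned.W[0], atol=1e-8)
            np.testing.assert_allclose(aligned.Z[s], aligned.Z[0], atol=1e-8)

    def test_distances_invariant(self):
        rng = np.random.default_rng(6)
        chain = make_chain(rng, n_draws=12)
        aligned = procrustes_align_chain(chain)
        for s in range(12):
            before = np.linalg.norm(
                chain.W[s][:, None] - chain.Z[s][None, :], axis=-1
            )
            after = np.linalg.norm(
                aligned.W[s][:, None] - aligned.Z[s][None, :], axis=-1
            )
            np.testing.assert_allclose(before, after, atol=1e-10)

    def test_log_likelihood_unchanged(self):
        rng = np.random.default_rng(7)
        chain = make_chain(rng, n_draws=5)
        y = rng.integers(0, 2, size=(chain.n_respondents, chain.n_items)).astype(float)
        aligned = procrustes_align_chain(chain)
        for s in range(5):
            assert log_likelihood(aligned.draw(s), y) == pytest.approx(
                log_likelihood(chain.draw(s), y), abs=1e-10
            )

    def test_map_summary(self):
        rng = np.random.default_rng(8)
        chain = make_chain(rng, n_draws=20)
        chain.log_posterior[:] = 0.0
        chain.log_posterior[[4, 9]] = 7.0  # tie: earliest wins
        fitted = posterior_summary(chain)
        assert fitted.map_index == 4
        np.testing.assert_allclose(fitted.beta_mean, chain.beta.mean(axis=0), atol=1e-12)


class TestMatchMaps:
    def test_self_match_is_identity(self):
        rng = np.random.default_rng(9)
        fitted = posterior_summary(make_chain(rng))
        matched = match_maps(fitted, fitted)
        np.testing.assert_allclose(matched.match_transform.rotation, np.eye(2), atol=1e-6)
        np.testing.assert_allclose(matched.W_mean, fitted.W_mean, atol=1e-8)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(10)
        ref = posterior_summary(make_chain(rng), align=False)
        motion = random_rigid(rng, reflect=True)
        other_chain = make_chain(np.random.default_rng(10))
        other_chain.W = np.array([motion.apply(w) for w in other_chain.W])
        other_chain.Z = np.array([motion.apply(z) for z in other_chain.Z])
        other = posterior_summary(other_chain, align=False)
        matched = match_maps(ref, other)
        np.testing.assert_allclose(matched.W_mean, ref.W_mean, atol=1e-8)
        np.testing.assert_allclose(matched.Z_mean, ref.Z_mean, atol=1e-8)

    def test_within_instrument_distances_unchanged(self):
        rng = np.random.default_rng(11)
        ref = posterior_summary(make_chain(rng))
        other = posterior_summary(make_chain(np.random.default_rng(99)))
        matched = match_maps(ref, other)
        before = np.linalg.norm(other.W_mean[:, None] - other.W_mean[None, :], axis=-1)
        after = np.linalg.norm(matched.W_mean[:, None] - matched.W_mean[None, :], axis=-1)
        np.testing.assert_allclose(before, after, atol=1e-10)

    def test_item_id_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        a = posterior_summary(make_chain(rng), item_ids=["a", "b", "c", "d", "e", "f"])
        b = posterior_summary(make_chain(rng), item_ids=["a", "b", "c", "d", "e", "X"])
        with pytest.raises(ValueError):
            match_maps(a, b)


class TestPoolChains:
    def test_pooled_chain_concatenates_in_common_frame(self):
        from lsirm.alignment import pool_chains

        rng = np.random.default_rng(13)
        c1 = make_chain(rng, n_draws=8)
        c2 = make_chain(rng, n_draws=6)
        pooled = pool_chains([c1, c2])
        assert len(pooled) == 14
        assert pooled.aligned
        # within-draw distances are untouched by the frame unification
        np.testing.assert_allclose(
            np.linalg.norm(pooled.W[8] [:, None] - pooled.W[8][None, :], axis=-1),
            np.linalg.norm(c2.W[0][:, None] - c2.W[0][None, :], axis=-1),
            atol=1e-10,
        )
        np.testing.assert_array_equal(pooled.beta[:8], c1.beta)
        np.testing.assert_array_equal(pooled.beta[8:], c2.beta)

    def test_estimator_multi_chain_deterministic(self):
        from lsirm.model import LSIRM

        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, size=(15, 6)).astype(float)
        kw = dict(n_iterations=300, burn_in=100, thin=2, n_chains=2, random_state=5)
        e1 = LSIRM(**kw).fit(y)
        e2 = LSIRM(**kw).fit(y)
        assert len(e1.chain_) == 2 * 100
        np.testing.assert_array_equal(e1.chain_.beta, e2.chain_.beta)
        np.testing.assert_array_equal(e1.W_, e2.W_)


class TestRigidTransform:
    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.array([[1.0, 0.5], [0.0, 1.0]]), np.zeros(2))

    def test_reflection_flag(self):
        assert RigidTransform(np.diag([1.0, -1.0]), np.zeros(2)).is_reflection
        assert not RigidTransform.identity(2).is_reflection
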