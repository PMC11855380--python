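"""Mixture solver correctness: E/M-step oracles, initialization, EM ascent,
the EM-limit of the heap-based solver, and the active-set cost advantage."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multisub.datatypes import ConfigError
from multisub.em import (HeapState, MixtureModel, VAR_FLOOR, assign, e_step,
                         fit_em, fit_em_star, fit_mixture, init_params,
                         m_step)
from multisub.synthetic import SynthConfig, generate
from sklearn.metrics import adjusted_rand_score


def _two_blobs(rng, n=100, d=2, sep=10.0):
    half = n // 2
    x = rng.standard_normal((n, d))
    x[:half, 0] -= sep / 2
    x[half:, 0] += sep / 2
    labels = np.repeat([1, 2], (half, n - half))
    return x, labels


class TestInit:
    def test_same_seed_identical(self, rng):
        x = rng.standard_normal((50, 3))
        a = init_params(x, 4, "kmeanspp", seed=9)
        b = init_params(x, 4, "kmeanspp", seed=9)
        assert np.array_equal(a.means, b.means)

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ConfigError):
            init_params(rng.standard_normal((3, 2)), 4)

    def test_k_below_two_warns(self, rng):
        with pytest.warns(UserWarning, match="two groups"):
            init_params(rng.standard_normal((5, 2)), 1)

    def test_k_equals_n_exhausts_samples(self, rng):
        x = rng.standard_normal((6, 2))
        model = init_params(x, 6, "kmeanspp", seed=0)
        # every distinct row chosen exactly once
        assert {tuple(row) for row in model.means} == {tuple(r) for r in x}

    def test_random_init_draws_distinct_samples(self, rng):
        x = rng.standard_normal((20, 2))
        model = init_params(x, 5, "random", seed=1)
        assert len({tuple(r) for r in model.means}) == 5

    def test_kmeanspp_spreads_across_far_pairs(self):
        """Two tight pairs far apart: D^2 sampling puts the second center in
        the other pair almost surely (exact probability ~ 1 - 1e-6)."""
        x = np.array([[0.0, 0.0], [0.1, 0.0], [100.0, 0.0], [100.1, 0.0]])
        hits = 0
        for s in range(1000):
            m = init_params(x, 2, "kmeanspp", seed=s)
            sides = {int(mu[0] > 50) for mu in m.means}
            hits += len(sides) == 2
        assert hits / 1000 >= 0.99


class TestESte:
    def test_single_component_unit_responsibility(self, rng):
        x = rng.standard_normal((10, 3))
        model = MixtureModel(1, [1.0], x.mean(0), x.var(0))
        r, _ = e_step(x, model)
        assert np.array_equal(r, np.ones((10, 1)))

    def test_symmetric_point_splits_evenly(self):
        model = MixtureModel(2, [0.5, 0.5], [[-1.0], [1.0]], [[1.0], [1.0]])
        r, _ = e_step(np.array([[0.0]]), model)
        assert np.allclose(r, [[0.5, 0.5]])

    def test_offset_point_known_posterior(self):
        # at x=1: phi(0) / (phi(0) + phi(2)) = 1 / (1 + e^-2)
        model = MixtureModel(2, [0.5, 0.5], [[-1.0], [1.0]], [[1.0], [1.0]])
        r, _ = e_step(np.array([[1.0]]), model)
        assert r[0, 1] == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)
        assert r[0, 1] == pytest.approx(0.8808, abs=1e-4)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_responsibility_rows_are_distributions(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((17, 4)) * 3
        model = init_params(x, 3, "random", seed=seed)
        r, _ = e_step(x, model)
        assert np.all(r >= 0) and np.all(r <= 1)
        assert np.abs(r.sum(axis=1) - 1.0).max() < 1e-10


class TestMStep:
    def test_hard_responsibilities_give_cluster_means(self, rng):
        x = rng.standard_normal((12, 3))
        r = np.zeros((12, 2))
        r[:7, 0] = 1.0
        r[7:, 1] = 1.0
        model = m_step(x, r)
        assert np.allclose(model.means[0], x[:7].mean(0))
        assert np.allclose(model.means[1], x[7:].mean(0))

    def test_uniform_responsibilities_collapse_to_global(self, rng):
        x = rng.standard_normal((20, 2))
        model = m_step(x, np.full((20, 4), 0.25))
        assert np.allclose(model.weights, 0.25)
        for c in range(4):
            assert np.allclose(model.means[c], x.mean(0))

    def test_matches_weighted_moment_oracle(self, rng):
        x = rng.standard_normal((15, 3))
        r = rng.dirichlet(np.ones(3), size=15)
        model = m_step(x, r)
        for c in range(3):
            nc = r[:, c].sum()
            mu = (r[:, c, None] * x).sum(0) / nc
            var = (r[:, c, None] * (x - mu) ** 2).sum(0) / nc
            assert np.abs(model.weights[c] - nc / 15).max() < 1e-10
            assert np.abs(model.means[c] - mu).max() < 1e-10
            assert np.abs(model.variances[c] - np.maximum(var, VAR_FLOOR)
                          ).max() < 1e-10

    def test_empty_component_reseeded(self, rng):
        x = rng.standard_normal((10, 2))
        r = np.zeros((10, 2))
        r[:, 0] = 1.0  # component 1 collapses
        model = m_step(x, r)
        assert np.abs(model.weights.sum() - 1.0) < 1e-12
        assert model.weights[1] > 0


class TestAssign:
    def test_argmax_row(self):
        a = assign(np.array([[0.2, 0.5, 0.3]]))
        assert a.labels.tolist() == [2]

    def test_tie_goes_to_lowest_index(self):
        a = assign(np.array([[0.5, 0.5]]))
        assert a.labels.tolist() == [1]

    def test_one_hot_identity(self):
        a = assign(np.eye(4))
        assert a.labels.tolist() == [1, 2, 3, 4]


class TestFitEM:
    def test_separated_blobs_recovered(self, rng):
        x, labels = _two_blobs(rng, n=200)
        _, _, asg = fit_em(x, 2, seed=0)
        assert adjusted_rand_score(labels, asg.labels) == 1.0

    def test_loglik_trace_monotone(self):
        for s in range(10):
            rng = np.random.default_rng(s)
            x = rng.standard_normal((80, 5)) + rng.choice(
                [-2.0, 2.0], size=(80, 1))
            model, _, _ = fit_em(x, 3, seed=s)
            diffs = np.diff(model.loglik_trace)
            assert diffs.min() >= -1e-8

    def test_n_equals_k_saturates(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 5.0]])
        model, _, asg = fit_em(x, 3, seed=0)
        assert sorted(asg.labels.tolist()) == [1, 2, 3]
        assert np.allclose(model.variances, VAR_FLOOR)

    def test_sample_permutation_invariance(self, rng):
        x, _ = _two_blobs(rng, n=60, d=4)
        init = init_params(x, 2, seed=3)
        perm = rng.permutation(60)
        m1, r1, _ = fit_em(x, 2, init_model=copy.deepcopy(init))
        init_p = MixtureModel(2, init.weights.copy(), init.means.copy(),
                              init.variances.copy())
        m2, r2, _ = fit_em(x[perm], 2, init_model=init_p)
        assert np.abs(r1[perm] - r2).max() < 1e-10
        assert np.abs(np.sort(m1.means, 0) - np.sort(m2.means, 0)).max() < 1e-10


class TestHeapState:
    def test_root_holds_maximal_key(self, rng):
        hs = HeapState(2, 10)
        keys = rng.standard_normal(10)
        clusters = rng.integers(0, 2, 10)
        hs.rebuild(np.arange(10), clusters, keys)
        for c in range(2):
            member_keys = keys[clusters == c]
            if len(member_keys):
                assert hs.root_key(c) == pytest.approx(member_keys.max())

    def test_active_and_settled_partition(self, cohort, rng):
        from multisub.stacking import stack, zscore_block
        joint = stack([zscore_block(m)[0] for m in cohort.omics])
        _, _, _, heap = fit_em_star(joint, 3, seed=1)
        settled = set(heap.settled)
        active = heap.active_set
        assert settled | active == set(range(joint.n_samples))
        assert settled & active == set()

    def test_settle_fraction_is_floor(self):
        hs = HeapState(1, 5)
        hs.rebuild(np.arange(5), np.zeros(5, int), np.arange(5.0))
        newly = hs.settle_top(0.5)
        assert len(newly) == 2        # floor(5 * 0.5)
        assert newly == [4, 3]        # highest keys settle first


class TestFitEMStar:
    def test_reduces_to_classical_em(self, rng):
        x, _ = _two_blobs(rng, n=120, d=6, sep=8.0)
        m1, r1, a1 = fit_em(x, 2, seed=4)
        m2, r2, a2, _ = fit_em_star(x, 2, seed=4, settle_quantile=1e-12)
        assert len(m1.loglik_trace) == len(m2.loglik_trace)
        assert np.abs(np.asarray(m1.loglik_trace)
                      - np.asarray(m2.loglik_trace)).max() < 1e-10
        assert np.array_equal(a1.labels, a2.labels)

    def test_settle_quantile_validated(self, rng):
        x = rng.standard_normal((10, 2))
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ConfigError):
                fit_em_star(x, 2, settle_quantile=bad)

    def test_agrees_with_em_on_separated_data(self):
        cfg = SynthConfig(n_samples=300, k_true=3,
                          omics_specs=[("mrna", 6, 6)], separation=8.0,
                          seed=0)
        data = generate(cfg)
        from multisub.stacking import zscore_block
        z, _ = zscore_block(data.omics[0])
        m1, _, a1 = fit_mixture(z, 3, method="em", seed=100, restarts=10)
        m2, _, a2 = fit_mixture(z, 3, method="em-star", seed=100,
                                restarts=10)[:3]
        assert adjusted_rand_score(a1.labels, a2.labels) >= 0.95
        rel = abs(m1.final_loglik - m2.final_loglik) / abs(m1.final_loglik)
        assert rel < 0.01

    def test_fewer_density_evaluations_than_em(self, rng):
        x, _ = _two_blobs(rng, n=300, d=50, sep=4.0)
        m_em, _, _ = fit_em(x, 2, seed=2)
        m_star, _, _, _ = fit_em_star(x, 2, seed=2)
        assert m_star.n_density_evals < m_em.n_density_evals

    def test_restart_wrapper_returns_best_loglik(self, rng):
        x, _ = _two_blobs(rng, n=80, d=3)
        single = [fit_em(x, 2, seed=10 + i)[0].final_loglik for i in range(4)]
        best, _, _ = fit_mixture(x, 2, method="em", seed=10, restarts=4)
        assert best.final_loglik == pytest.approx(max(single))
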