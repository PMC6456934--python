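"""Unit tests for affinities, energy, gradient and the optimizer pieces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group

from tsee import (
    EmbeddingConfig,
    build_affinities,
    combined_laplacian,
    fit_tsee,
    pairwise_sq_distances,
    tsee_energy,
    tsee_gradient,
)
from tsee.core import (
    ArmijoStep,
    _backtrack,
    armijo_step,
    attractive_laplacian_factor,
    resolve_sigma,
    spectral_direction,
)

from conftest import make_dataset


class TestPairwiseSqDistances:
    def test_three_four_five_triangle(self):
        d2 = pairwise_sq_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d2[0, 1] == d2[1, 0] == 25.0
        assert d2[0, 0] == d2[1, 1] == 0.0

    def test_identical_rows_give_zero_matrix(self):
        d2 = pairwise_sq_distances(np.ones((4, 3)))
        assert np.all(d2 == 0.0)

    def test_matches_double_loop(self, rng):
        pts = rng.normal(size=(5, 3))
        d2 = pairwise_sq_distances(pts)
        for i in range(5):
            for j in range(5):
                expected = np.sum((pts[i] - pts[j]) ** 2)
                assert abs(d2[i, j] - expected) < 1e-12

    def test_nonfinite_input_names_row(self):
        pts = np.ones((3, 2))
        pts[1, 0] = np.nan
        with pytest.raises(ValueError, match="row 1"):
            pairwise_sq_distances(pts)


class TestBuildAffinities:
    def test_two_cells_normalize_to_half_each(self):
        ds = make_dataset(n_cells=2, n_stages=2)
        model = build_affinities(ds, beta=0.0, sigma=1.0)
        assert np.allclose(model.w_plus, [[0, 0.5], [0.5, 0]])
        assert abs(model.w_plus.sum() - 1.0) < 1e-12

    def test_beta_zero_reduces_to_plain_disparity_weights(self, small_dataset):
        model = build_affinities(small_dataset, beta=0.0, sigma=0.7)
        assert np.all(model.t_side * 0.0 == 0.0)
        dist = np.sqrt(pairwise_sq_distances(small_dataset.expression))
        assert np.allclose(model.w_minus, dist / dist.sum(), atol=1e-12)

    def test_hand_computed_four_cell_instance(self):
        y = np.array([[0.0, 0.0], [0.3, 0.1], [0.9, 0.8], [1.0, 1.0]])
        stage_time = np.array([0.0, 0.0, 1.0, 1.0])
        ds = make_dataset(n_cells=4, n_stages=2)
        ds.expression = y
        ds.stage_time = stage_time
        ds.stage_index = np.array([1, 1, 2, 2])
        beta, sigma = 10.0, 0.5
        model = build_affinities(ds, beta=beta, sigma=sigma)
        # brute-force double loop over all pairs
        n = 4
        wp = np.zeros((n, n)); wm = np.zeros((n, n)); side = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d2 = np.sum((y[i] - y[j]) ** 2)
                wp[i, j] = np.exp(-d2 / (2 * sigma**2))
                wm[i, j] = np.sqrt(d2)
                side[i, j] = abs(stage_time[i] - stage_time[j])
        n_minus = 1.0 / (wm + beta * side).sum()
        assert np.allclose(model.w_plus, wp / wp.sum(), atol=1e-12)
        assert np.allclose(model.w_minus, wm * n_minus, atol=1e-12)
        assert np.allclose(model.t_side, side * n_minus, atol=1e-12)

    def test_custom_side_distance_replaces_time_intervals(self, small_dataset, rng):
        n = small_dataset.n_cells
        raw = rng.uniform(0, 1, size=(n, n))
        side = (raw + raw.T) / 2
        np.fill_diagonal(side, 0.0)
        model = build_affinities(small_dataset, beta=2.0, sigma=1.0, side_distance=side)
        assert np.allclose(
            model.t_side / model.t_side.sum() * side.sum(), side, atol=1e-10
        )

    def test_sigma_must_be_positive(self, small_dataset):
        with pytest.raises(ValueError, match="sigma"):
            build_affinities(small_dataset, beta=1.0, sigma=0.0)

    def test_identical_rows_degenerate(self):
        ds = make_dataset(n_cells=3, n_stages=1)
        ds.expression = np.ones((3, 2))
        ds.stage_time = np.zeros(3)
        ds.stage_index = np.ones(3, dtype=int)
        with pytest.raises(ValueError, match="repulsive normalizer"):
            build_affinities(ds, beta=1.0, sigma=1.0)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(beta=st.floats(min_value=0.0, max_value=1000.0), seed=st.integers(0, 100))
def test_normalization_conservation_property(beta, seed):
    """Off-diagonal sums of w^P and of (w^N + beta*t) are exactly 1."""
    ds = make_dataset(n_cells=8, n_stages=3, seed=seed)
    model = build_affinities(ds, beta=beta, sigma=0.6)
    assert abs(model.w_plus.sum() - 1.0) < 1e-10
    assert abs((model.w_minus + beta * model.t_side).sum() - 1.0) < 1e-10
    for m in (model.w_plus, model.w_minus, model.t_side):
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert m.min() >= 0.0


class TestEnergy:
    def test_coincident_points_give_lambda(self, small_dataset):
        model = build_affinities(small_dataset, beta=5.0, sigma=0.8)
        x = np.ones((small_dataset.n_cells, 2))
        lam = 3.7
        # attractive term vanishes; exp(0)=1 and the repulsive sum is normalized to 1
        assert abs(tsee_energy(x, model, lam) - lam) < 1e-10

    def test_lambda_zero_is_attractive_term_only(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=5.0, sigma=0.8)
        x = rng.normal(size=(small_dataset.n_cells, 2))
        d2 = pairwise_sq_distances(x)
        assert abs(tsee_energy(x, model, 0.0) - (model.w_plus * d2).sum()) < 1e-12

    def test_matches_double_loop(self, rng):
        ds = make_dataset(n_cells=5, n_stages=2, seed=7)
        beta, lam = 10.0, 4.0
        model = build_affinities(ds, beta=beta, sigma=0.9)
        x = rng.normal(size=(5, 2))
        expected = 0.0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                d2 = np.sum((x[i] - x[j]) ** 2)
                expected += model.w_plus[i, j] * d2
                expected += lam * (model.w_minus[i, j] + beta * model.t_side[i, j]) * np.exp(-d2)
        assert abs(tsee_energy(x, model, lam) - expected) < 1e-12

    def test_rigid_motion_invariance(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=10.0, sigma=0.8)
        x = rng.normal(size=(small_dataset.n_cells, 2))
        e0 = tsee_energy(x, model, 10.0)
        rot = ortho_group.rvs(2, random_state=3)
        shifted = x @ rot + rng.normal(size=(1, 2))
        assert abs(tsee_energy(shifted, model, 10.0) - e0) < 1e-10

    def test_dimension_mismatch_raises(self, small_dataset):
        model = build_affinities(small_dataset, beta=1.0, sigma=1.0)
        with pytest.raises(ValueError, match="coordinates"):
            tsee_energy(np.zeros((3, 2)), model, 1.0)


class TestLaplacianAndGradient:
    def test_lambda_zero_gives_attractive_laplacian(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=1.0, sigma=0.8)
        x = rng.normal(size=(small_dataset.n_cells, 2))
        lap = combined_laplacian(x, model, 0.0)
        wp = model.w_plus
        assert np.allclose(lap, np.diag(wp.sum(axis=1)) - wp, atol=1e-12)

    def test_rows_sum_to_zero(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=10.0, sigma=0.8)
        x = rng.normal(size=(small_dataset.n_cells, 2))
        lap = combined_laplacian(x, model, 10.0)
        assert np.allclose(lap.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(lap, lap.T)

    def test_gradient_zero_for_coincident_points(self, small_dataset):
        model = build_affinities(small_dataset, beta=10.0, sigma=0.8)
        x = np.ones((small_dataset.n_cells, 2)) * 0.3
        assert np.allclose(tsee_gradient(x, model, 10.0), 0.0, atol=1e-12)

    def test_translation_invariance_of_gradient(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=10.0, sigma=0.8)
        x = rng.normal(size=(small_dataset.n_cells, 2))
        g0 = tsee_gradient(x, model, 10.0)
        g1 = tsee_gradient(x + np.array([2.5, -1.0]), model, 10.0)
        assert np.allclose(g0, g1, atol=1e-10)

    @pytest.mark.parametrize("beta", [0.0, 10.0])
    def test_gradient_matches_finite_differences(self, beta, rng):
        ds = make_dataset(n_cells=6, n_stages=3, seed=11)
        model = build_affinities(ds, beta=beta, sigma=0.7)
        lam = 7.3
        x = rng.normal(scale=0.5, size=(6, 2))
        g = tsee_gradient(x, model, lam)
        fd = np.zeros_like(x)
        h = 1e-6
        for i in range(x.shape[0]):
            for k in range(x.shape[1]):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                fd[i, k] = (tsee_energy(xp, model, lam) - tsee_energy(xm, model, lam)) / (2 * h)
        assert np.linalg.norm(g - fd) / max(np.linalg.norm(fd), 1e-12) < 1e-4


class TestSpectralDirection:
    def test_factorization_succeeds_and_zero_gradient_maps_to_zero(self, small_dataset):
        model = build_affinities(small_dataset, beta=1.0, sigma=0.8)
        state = attractive_laplacian_factor(model)
        assert state.mu > 0
        p = spectral_direction(state, np.zeros((small_dataset.n_cells, 2)))
        assert np.allclose(p, 0.0)

    def test_descent_direction(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=1.0, sigma=0.8)
        state = attractive_laplacian_factor(model)
        for _ in range(5):
            g = rng.normal(size=(small_dataset.n_cells, 2))
            p = spectral_direction(state, g)
            assert float((p * g).sum()) < 0.0

    def test_matches_dense_solve(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=1.0, sigma=0.8)
        state = attractive_laplacian_factor(model)
        wp = model.w_plus
        lp = np.diag(wp.sum(axis=1)) - wp
        b = lp + state.mu * np.eye(lp.shape[0])
        g = rng.normal(size=(small_dataset.n_cells, 2))
        p = spectral_direction(state, g)
        expected = np.linalg.solve(b, -g)
        assert np.allclose(p, expected, atol=1e-10)

    def test_nonfinite_gradient_rejected(self, small_dataset):
        model = build_affinities(small_dataset, beta=1.0, sigma=0.8)
        state = attractive_laplacian_factor(model)
        g = np.full((small_dataset.n_cells, 2), np.inf)
        with pytest.raises(ValueError, match="non-finite"):
            spectral_direction(state, g)


class TestArmijo:
    def test_quadratic_backtracking_sequence(self):
        # E(x)=x^2 at x=1, p=-2, g=2: alpha=1 lands on E=1 (insufficient), alpha=0.5 on E=0
        energy = lambda x: float(x**2)
        step = _backtrack(energy, np.array(1.0), np.array(-2.0), slope=-4.0,
                          energy_old=1.0, c=1e-4, shrink=0.5, alpha0=1.0)
        assert step.alpha == 0.5
        assert step.energy_new == 0.0
        assert not step.stalled

    def test_first_trial_accepted_for_small_step(self, small_dataset, rng):
        model = build_affinities(small_dataset, beta=1.0, sigma=0.8)
        x = rng.normal(size=(small_dataset.n_cells, 2))
        g = tsee_gradient(x, model, 10.0)
        cfg = EmbeddingConfig()
        step = armijo_step(x, -g, g, model, 10.0, cfg, warm_alpha=1e-6)
        assert step.alpha == 1e-6
        assert step.energy_new <= tsee_energy(x, model, 10.0)

    def test_stall_returns_zero_step(self):
        # energy rises along the (falsely declared) descent direction
        uphill = lambda x: 1.0 + abs(float(x))
        step = _backtrack(uphill, np.array(0.0), np.array(1.0), slope=-1.0,
                          energy_old=1.0, c=1e-4, shrink=0.5, alpha0=1.0)
        assert step.stalled
        assert step.alpha == 0.0

    def test_non_descent_direction_rejected(self):
        with pytest.raises(ValueError, match="descent"):
            _backtrack(lambda x: 0.0, np.array(0.0), np.array(1.0), slope=0.0,
                       energy_old=0.0, c=1e-4, shrink=0.5, alpha0=1.0)


class TestFit:
    def test_energy_trace_non_increasing_and_descent(self, small_dataset):
        result = fit_tsee(small_dataset, EmbeddingConfig(max_iter=60))
        trace = np.asarray(result.energy_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert np.all(trace >= 0.0)
        assert all(v < 0 for v in result.inner_products)

    def test_deterministic_given_config(self, small_dataset):
        a = fit_tsee(small_dataset, EmbeddingConfig(max_iter=30))
        b = fit_tsee(small_dataset, EmbeddingConfig(max_iter=30))
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.energy_trace == b.energy_trace

    def test_permutation_equivariance(self):
        ds = make_dataset(n_cells=10, n_stages=2, seed=5)
        cfg = EmbeddingConfig(max_iter=40, sigma_policy="fixed:0.8")
        rng = np.random.default_rng(0)
        x0 = rng.normal(scale=1e-2, size=(10, 2))
        res = fit_tsee(ds, cfg, x0=x0)
        perm = rng.permutation(10)
        ds_p = make_dataset(n_cells=10, n_stages=2, seed=5)
        ds_p.expression = ds.expression[perm]
        ds_p.stage_index = ds.stage_index[perm]
        ds_p.stage_time = ds.stage_time[perm]
        res_p = fit_tsee(ds_p, cfg, x0=x0[perm])
        assert np.allclose(res_p.coordinates, res.coordinates[perm], atol=1e-8)

    def test_random_init_uses_seed(self, small_dataset):
        cfg_a = EmbeddingConfig(init_policy="random", seed=1, max_iter=5)
        cfg_b = EmbeddingConfig(init_policy="random", seed=2, max_iter=5)
        a = fit_tsee(small_dataset, cfg_a)
        b = fit_tsee(small_dataset, cfg_b)
        assert not np.array_equal(a.coordinates, b.coordinates)

    def test_median_sigma_resolution(self, small_dataset):
        sigma = resolve_sigma(small_dataset.expression, EmbeddingConfig())
        from scipy.spatial.distance import pdist
        assert sigma == pytest.approx(np.median(pdist(small_dataset.expression)))
        fixed = resolve_sigma(small_dataset.expression, EmbeddingConfig(sigma_policy="fixed:2.5"))
        assert fixed == 2.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingConfig(lam=-1.0)
        with pytest.raises(ValueError):
            EmbeddingConfig(sigma_policy="fixed:-1")
        with pytest.raises(ValueError):
            EmbeddingConfig(init_policy="banana")
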