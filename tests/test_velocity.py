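"""Denoising graph, temporal-regression velocity, and decay-rate bounds."""

import numpy as np
import pytest

from velogrn.cell_times import CellTimes
from velogrn.velocity import (
    DenoisingGraph,
    build_denoising_graph,
    decay_bound,
    denoise,
    estimate_velocity,
    sliding_decay,
)


def _identity_graph(n):
    return DenoisingGraph(
        neighbors=[np.array([i]) for i in range(n)],
        weights=[np.array([1.0]) for _ in range(n)],
        selected_pcs=1,
        selected_k=1,
        selection_mse=0.0,
    )


def _chain_graph(n, k=4):
    """Neighbors are the k nearest cells by index, equally weighted."""
    neighbors, weights = [], []
    for i in range(n):
        nbr = [j for j in sorted(range(n), key=lambda j: abs(j - i)) if j != i][:k]
        neighbors.append(np.array(nbr))
        weights.append(np.full(k, 1.0 / k))
    return DenoisingGraph(neighbors, weights, 1, k, 0.0)


class TestDenoisingGraph:
    def test_single_candidate_pair_is_selected(self, rng):
        X = rng.poisson(10, size=(40, 8)).astype(float)
        graph = build_denoising_graph(X, [2], [5], seed=0)
        assert (graph.selected_pcs, graph.selected_k) == (2, 5)

    def test_weights_sum_to_one(self, rng):
        X = rng.poisson(10, size=(40, 8)).astype(float)
        graph = build_denoising_graph(X, [2, 3], [5, 10], seed=0)
        for w in graph.weights:
            assert np.isclose(w.sum(), 1.0, atol=1e-12)

    def test_denoising_reduces_error_to_true_signal(self, rng):
        u = rng.uniform(1, 3, 200)
        v = rng.uniform(1, 3, 50)
        signal = 5 * np.outer(u, v)
        X = rng.poisson(signal).astype(float)
        graph = build_denoising_graph(X, [1, 2], [10, 25], seed=0)
        Xd = denoise(X, graph)
        assert np.mean((Xd.X - signal) ** 2) < np.mean((X - signal) ** 2)


class TestDenoise:
    def test_identity_graph_is_a_fixed_point(self, rng):
        X = rng.poisson(5, size=(6, 4)).astype(float)
        out = denoise(X, _identity_graph(6))
        assert np.array_equal(out.X, X)

    def test_mutual_neighbors_of_identical_cells_unchanged(self):
        X = np.array([[2.0, 3.0], [2.0, 3.0]])
        graph = DenoisingGraph(
            neighbors=[np.array([1]), np.array([0])],
            weights=[np.array([1.0]), np.array([1.0])],
            selected_pcs=1, selected_k=1, selection_mse=0.0,
        )
        assert np.array_equal(denoise(X, graph).X, X)

    def test_hand_weighted_average(self):
        X = np.array([[0.0, 10.0], [4.0, 2.0], [8.0, 6.0]])
        graph = DenoisingGraph(
            neighbors=[np.array([1, 2])] * 3,
            weights=[np.array([0.5, 0.5])] * 3,
            selected_pcs=1, selected_k=2, selection_mse=0.0,
        )
        assert np.allclose(denoise(X, graph).X, [[6.0, 4.0]] * 3)


class TestEstimateVelocity:
    def test_constant_expression_gives_zero_velocity(self, rng):
        X = np.full((10, 3), 7.0)
        times = CellTimes(t=np.linspace(0, 9, 10))
        vel = estimate_velocity(X, times, _chain_graph(10))
        assert np.allclose(vel.dXdt[~vel.missing], 0.0)

    def test_linear_expression_recovers_exact_slope(self, rng):
        t = np.linspace(0, 9, 10)
        X = np.column_stack([2.0 * t, 5.0 - 0.5 * t, np.full(10, 3.0)])
        vel = estimate_velocity(X, CellTimes(t=t), _chain_graph(10))
        ok = ~vel.missing
        # closed-form no-intercept OLS slope on each neighborhood
        assert np.allclose(vel.dXdt[ok, 0], 2.0, atol=1e-9)
        assert np.allclose(vel.dXdt[ok, 1], -0.5, atol=1e-9)
        assert np.allclose(vel.dXdt[ok, 2], 0.0, atol=1e-9)

    def test_matches_brute_force_ols_oracle(self, rng):
        t = np.sort(rng.uniform(0, 10, 30))
        X = rng.normal(size=(30, 4)) + 5
        graph = _chain_graph(30, k=6)
        vel = estimate_velocity(X, CellTimes(t=t), graph)
        c = 13
        dt = t[graph.neighbors[c]] - t[c]
        dX = X[graph.neighbors[c]] - X[c]
        beta = np.linalg.lstsq(dt[:, None], dX, rcond=None)[0][0]
        assert np.allclose(vel.dXdt[c], beta, atol=1e-9)

    def test_time_shift_and_scale_equivariance(self, rng):
        t = np.sort(rng.uniform(0, 10, 25))
        X = rng.normal(size=(25, 3)) + 5
        graph = _chain_graph(25, k=5)
        base = estimate_velocity(X, CellTimes(t=t), graph).dXdt
        shifted = estimate_velocity(X, CellTimes(t=t + 37.0), graph).dXdt
        scaled = estimate_velocity(X, CellTimes(t=3.0 * t), graph).dXdt
        assert np.allclose(base, shifted, equal_nan=True)
        assert np.allclose(base / 3.0, scaled, equal_nan=True)

    def test_wrapped_time_uses_minimal_circular_difference(self):
        # two cells at 1 and 87 minutes on an 88-minute circle are 2 apart
        t = np.array([1.0, 87.0, 3.0])
        X = np.array([[0.0], [1.0], [2.0]])
        graph = _chain_graph(3, k=2)
        vel = estimate_velocity(X, CellTimes(t=t), graph, wrap=88.0)
        assert np.all(np.isfinite(vel.dXdt[~vel.missing]))

    def test_zero_dt_neighborhood_is_missing_not_zero(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        times = CellTimes(t=np.zeros(4))
        vel = estimate_velocity(X, times, _chain_graph(4, k=2))
        assert vel.missing.all()
        assert np.isnan(vel.dXdt).all()

    def test_true_velocity_recovered_on_simulated_kinetics(self, dense_simulation):
        # noiseless expression, true times: the local regression slope should
        # track the analytic velocity alpha - lambda * X closely
        exp = dense_simulation
        order = np.argsort(exp.true_times)
        X = exp.true_expression[order]
        t = exp.true_times[order]
        graph = _chain_graph(len(t), k=10)
        vel = estimate_velocity(X, CellTimes(t=t), graph)
        truth = exp.true_velocity[order]
        ok = ~vel.missing
        rs = [
            np.corrcoef(vel.dXdt[ok, j], truth[ok, j])[0, 1]
            for j in range(X.shape[1])
        ]
        assert np.median(rs) >= 0.9


class TestDecayBound:
    def test_pure_decay_recovers_rate_exactly(self, rng):
        x = rng.uniform(1, 10, 100)
        v = -0.1 * x
        assert decay_bound(x, v) == pytest.approx(0.1, abs=1e-9)

    def test_production_dominated_data_clamps_to_zero(self, rng):
        x = rng.uniform(1, 10, 50)
        v = np.abs(rng.normal(1, 0.1, 50))
        assert decay_bound(x, v) == 0.0

    def test_bound_is_conservative_on_simulated_kinetics(self, dense_simulation):
        exp = dense_simulation
        lam_true = exp.kinetics.lambda_base
        for j in range(exp.true_expression.shape[1]):
            lam_min = decay_bound(
                exp.true_expression[:, j], exp.true_velocity[:, j]
            )
            assert 0.0 <= lam_min <= lam_true[j] + 1e-9

    def test_too_few_positive_cells_rejected(self):
        with pytest.raises(ValueError):
            decay_bound(np.ones(5), -np.ones(5))

    def test_no_positive_expression_returns_missing(self):
        assert np.isnan(decay_bound(np.zeros(30), np.zeros(30)))


class TestSlidingDecay:
    def test_stationary_kinetics_give_stable_windows(self, rng):
        # steady state: x fluctuates around alpha/lambda, v = alpha - lambda*x
        n = 2000
        t = np.sort(rng.uniform(0, 100, n))
        x = rng.normal(50.0, 2.0, n).clip(1)
        v = 5.0 - 0.1 * x
        bound = sliding_decay(x, v, t, window_width=20.0, step=10.0)
        vals = bound.lambda_min[np.isfinite(bound.lambda_min)]
        assert len(vals) >= 3
        assert vals.max() <= 2.0 * max(vals.min(), 1e-6)

    def test_step_change_in_decay_rate_is_visible(self, rng):
        n = 4000
        t = np.sort(rng.uniform(0, 40, n))
        lam = np.where(t < 20, 0.03, 0.07)
        x = rng.uniform(20, 80, n)
        v = -lam * x  # pure decay on both sides of the change point
        bound = sliding_decay(x, v, t, window_width=10.0, step=5.0)
        early = bound.lambda_min[bound.window_centers < 15]
        late = bound.lambda_min[bound.window_centers > 25]
        assert np.nanmax(early) < np.nanmin(late)

    def test_giant_step_degenerates_to_global_bound(self, rng):
        x = rng.uniform(1, 10, 100)
        v = -0.05 * x
        t = np.sort(rng.uniform(0, 10, 100))
        bound = sliding_decay(x, v, t, window_width=5.0, step=100.0)
        assert bound.lambda_min.shape[0] == 1
        assert bound.lambda_min[0] == pytest.approx(decay_bound(x, v))
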