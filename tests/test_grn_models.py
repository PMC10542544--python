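"""Forward contracts of the masked neural GRN model variants."""

import numpy as np
import pytest

from velogrn.grn_models import (
    BiophysicalModel,
    DecayModule,
    DynamicalGRNModel,
    PerturbationSpec,
    StaticGRNModel,
    biophysical_forward,
    decay_forward,
    dynamical_forward,
    make_trajectories,
    predict_forward,
    static_forward,
)


def _mask(g, k, rng=None, density=0.5):
    rng = rng or np.random.default_rng(0)
    M = (rng.random((g, k)) < density).astype(float)
    M[np.arange(k) % g, np.arange(k)] = 1
    return M


class TestStatic:
    def test_scalar_chain_hand_arithmetic(self):
        m = StaticGRNModel(np.ones((1, 1)), output_mode="counts", seed=0)
        m.encoder.W_E.data[:] = 2.0
        m.W_2.data[:] = 1.0
        m.W_D.data[:] = 0.5
        out, h_tf = static_forward(m, np.array([[3.0]]))
        assert h_tf[0, 0] == 6.0
        assert out[0, 0] == 3.0

    def test_zero_input_propagates_to_zero(self, rng):
        m = StaticGRNModel(_mask(6, 3, rng), seed=1)
        out, h_tf = static_forward(m, np.zeros((4, 6)))
        assert np.all(out == 0) and np.all(h_tf == 0)

    def test_masked_gene_has_zero_influence_on_its_tf(self, rng):
        mask = _mask(6, 3, rng)
        gene, tf = np.argwhere(mask == 0)[0]
        m = StaticGRNModel(mask, seed=2)
        X = rng.uniform(1, 2, (5, 6))
        _, h0 = static_forward(m, X)
        X2 = X.copy()
        X2[:, gene] += 10.0
        _, h1 = static_forward(m, X2)
        assert np.allclose(h0[:, tf], h1[:, tf])

    def test_counts_mode_output_nonnegative(self, rng):
        m = StaticGRNModel(_mask(6, 3, rng), output_mode="counts", seed=3)
        out, _ = static_forward(m, rng.uniform(0, 3, (10, 6)))
        assert np.all(out >= 0)


class TestDynamical:
    def test_zero_recurrence_collapses_to_static(self, rng):
        mask = _mask(5, 2, rng)
        dyn = DynamicalGRNModel(mask, output_mode="counts", seed=4)
        dyn.W_h2.data[:] = 0.0
        stat = StaticGRNModel(mask, output_mode="counts", seed=99)
        stat.encoder.W_E.data = dyn.encoder.W_E.data.copy()
        stat.W_2.data = dyn.W_i2.data.copy()
        stat.W_D.data = dyn.W_D.data.copy()
        seq = rng.uniform(0, 2, (3, 4, 5))
        outs, _ = dynamical_forward(dyn, seq)
        for t in range(3):
            s_out, _ = static_forward(stat, seq[t])
            assert np.allclose(outs[t], s_out)

    def test_scalar_two_step_hand_unroll(self):
        m = DynamicalGRNModel(np.ones((1, 1)), output_mode="counts", seed=0)
        m.encoder.W_E.data[:] = 1.0
        m.W_i2.data[:] = 2.0
        m.W_h2.data[:] = 0.5
        m.W_D.data[:] = 1.0
        seq = np.array([[[1.0]], [[2.0]]])
        outs, _ = dynamical_forward(m, seq)
        # h1 = relu(1*2) = 2 -> out 2; h2 = relu(2*2 + 2*0.5) = 5 -> out 5
        assert outs[0][0, 0] == 2.0
        assert outs[1][0, 0] == 5.0

    def test_zero_sequence_gives_zero_output(self, rng):
        m = DynamicalGRNModel(_mask(5, 2, rng), seed=5)
        outs, h = dynamical_forward(m, np.zeros((4, 3, 5)))
        assert np.all(outs == 0) and np.all(h == 0)

    def test_empty_trajectory_rejected(self, rng):
        m = DynamicalGRNModel(_mask(5, 2, rng), seed=5)
        with pytest.raises(ValueError):
            dynamical_forward(m, np.zeros((0, 3, 5)))


class TestDecayModule:
    def test_rates_strictly_positive(self, rng):
        dec = DecayModule(6, seed=0)
        lam, _ = decay_forward(dec, rng.uniform(0, 3, (4, 5, 6)))
        assert np.all(lam > 0)

    def test_zero_expression_gives_zero_decay_velocity(self, rng):
        dec = DecayModule(6, seed=0)
        _, vel = decay_forward(dec, np.zeros((2, 3, 6)))
        assert np.all(vel == 0)

    def test_decay_velocity_nonpositive(self, rng):
        dec = DecayModule(6, seed=1)
        _, vel = decay_forward(dec, rng.uniform(0, 3, (4, 5, 6)))
        assert np.all(vel <= 0)

    def test_softplus_at_zero_is_log_two(self):
        from velogrn._autograd import Tensor

        assert Tensor(0.0).softplus().data == pytest.approx(np.log(2.0), abs=1e-15)

    def test_rate_scale_scales_rates(self, rng):
        X = rng.uniform(0, 3, (1, 4, 6))
        lam1, _ = decay_forward(DecayModule(6, seed=2, rate_scale=1.0), X)
        lam01, _ = decay_forward(DecayModule(6, seed=2, rate_scale=0.1), X)
        assert np.allclose(lam01, 0.1 * lam1)


class TestBiophysical:
    def test_decomposition_identity_holds_exactly(self, rng):
        m = BiophysicalModel(_mask(8, 3, rng), seed=0)
        seq = rng.uniform(0, 3, (4, 5, 8))
        vel, alpha, lam, _ = biophysical_forward(m, seq)
        assert np.array_equal(vel, alpha - lam * seq)
        assert np.all(alpha >= 0)
        assert np.all(-lam * seq <= 0)

    def test_perturbation_identity_is_noop(self, rng):
        m = BiophysicalModel(_mask(8, 3, rng), seed=1)
        seq = rng.uniform(0, 3, (3, 4, 8))
        base = biophysical_forward(m, seq)[0]
        pert = biophysical_forward(m, seq, PerturbationSpec.identity(3))[0]
        assert np.array_equal(base, pert)

    def test_knockout_removes_tf_sensitivity(self, rng):
        mask = _mask(8, 3, rng)
        m = BiophysicalModel(mask, seed=2)
        seq = rng.uniform(1, 3, (2, 4, 8))
        ko = PerturbationSpec.knockout(3, [1])
        # the transcription (alpha) component must lose all sensitivity to
        # genes that feed only TF 1; the decay module is unmasked by design
        base = biophysical_forward(m, seq, ko)[1]
        only_tf1 = np.where((mask[:, 1] == 1) & (mask[:, [0, 2]].sum(1) == 0))[0]
        if len(only_tf1) == 0:
            pytest.skip("mask draw left no TF1-exclusive gene")
        seq2 = seq.copy()
        seq2[..., only_tf1] += 5.0
        assert np.allclose(base, biophysical_forward(m, seq2, ko)[1])


class TestPredictForward:
    class _ZeroVelocity:
        output_mode = "velocity"

        def step(self, X, state, perturb=None):
            return np.zeros_like(X), state

    class _PureDecay:
        output_mode = "velocity"

        def __init__(self, lam):
            self.lam = lam

        def step(self, X, state, perturb=None):
            return -self.lam * X, state

    def test_zero_velocity_model_is_a_fixed_point(self):
        X0 = np.array([[1.0, 2.0]])
        seq = predict_forward(self._ZeroVelocity(), X0, steps=5, dt=1.0)
        assert np.all(seq == X0)

    def test_euler_decay_matches_closed_form_within_known_error(self):
        # lambda=0.1, dt=1: (0.9)^10 vs e^-1 -> relative error ~5.2% < 6%
        X0 = np.array([[100.0]])
        seq = predict_forward(self._PureDecay(0.1), X0, steps=10, dt=1.0)
        exact = 100.0 * np.exp(-1.0)
        assert abs(seq[-1][0, 0] - exact) / exact < 0.06

    def test_negative_update_clamps_at_zero(self):
        X0 = np.array([[0.05]])
        seq = predict_forward(self._PureDecay(30.0), X0, steps=3, dt=1.0)
        assert np.all(seq >= 0)
        assert seq[-1][0, 0] == 0.0

    def test_counts_mode_feeds_predictions_back(self, rng):
        m = StaticGRNModel(_mask(5, 2, rng), output_mode="counts", seed=3)
        X0 = rng.uniform(0, 2, (2, 5))
        seq = predict_forward(m, X0, steps=2)
        step1, _ = static_forward(m, X0)
        step2, _ = static_forward(m, step1)
        assert np.allclose(seq[1], step1)
        assert np.allclose(seq[2], step2)


class TestMakeTrajectories:
    def test_length_one_trajectories_are_single_cells(self, rng):
        X = rng.uniform(size=(30, 4))
        t = rng.uniform(0, 10, 30)
        batches = make_trajectories(X, t, bin_width=1.0, length=1, batch=8, seed=0)
        assert all(tb.X_seq.shape[0] == 1 for tb in batches)

    def test_offset_counting_bound(self, rng):
        # 60 one-minute bins and length 10 allow at most 51 start offsets
        t = np.repeat(np.arange(60.0) + 0.5, 3)
        X = rng.uniform(size=(len(t), 2))
        batches = make_trajectories(X, t, bin_width=1.0, length=10, batch=1000, seed=0)
        n_traj = sum(tb.X_seq.shape[1] for tb in batches)
        assert n_traj <= 51

    def test_seeded_determinism(self, rng):
        X = rng.uniform(size=(50, 3))
        t = rng.uniform(0, 20, 50)
        a = make_trajectories(X, t, bin_width=2.0, length=5, batch=10, seed=9)
        b = make_trajectories(X, t, bin_width=2.0, length=5, batch=10, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.cell_indices, tb.cell_indices)

    def test_span_shorter_than_length_rejected(self, rng):
        with pytest.raises(ValueError):
            make_trajectories(
                rng.uniform(size=(10, 2)), np.linspace(0, 3, 10),
                bin_width=1.0, length=10, batch=5, seed=0,
            )


class TestCheckpoints:
    def test_biophysical_round_trip_preserves_outputs(self, tmp_path, rng):
        from velogrn.grn_models import load_model, save_model

        m = BiophysicalModel(_mask(6, 2, rng), seed=0)
        seq = rng.uniform(0, 2, (3, 4, 6))
        before = biophysical_forward(m, seq)[0]
        path = tmp_path / "model.h5"
        save_model(m, path)
        back = load_model(path)
        assert np.array_equal(biophysical_forward(back, seq)[0], before)

    def test_static_round_trip(self, tmp_path, rng):
        from velogrn.grn_models import load_model, save_model

        m = StaticGRNModel(_mask(5, 2, rng), output_mode="velocity", seed=1)
        X = rng.uniform(0, 2, (4, 5))
        before, _ = static_forward(m, X)
        save_model(m, tmp_path / "m.h5")
        back = load_model(tmp_path / "m.h5")
        out, _ = static_forward(back, X)
        assert np.array_equal(out, before)
        assert np.array_equal(back.encoder.mask, m.encoder.mask)
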