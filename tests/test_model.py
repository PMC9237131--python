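"""Network forward pass, evidential head, NIG loss, bounds, and gradients."""
import numpy as np
import pytest
from scipy.stats import t as student_t

from glyforecast.autodiff import Tensor
from glyforecast.datatypes import InvalidArgumentError
from glyforecast.features import TargetScaler
from glyforecast.model import (EPS, GlucoseModel, ModelConfig, NigOutput,
                               attention_output, attention_weights,
                               evidential_head, gru_cell,
                               init_weights, nig_nll_loss, nig_uncertainty,
                               predict_with_bounds, _wrap)

CFG = ModelConfig(input_dim=3, hidden=4, hidden2=4, v_dim=4)


class TestGru:
    def test_scalar_cell_matches_hand_computation(self):
        """1-dim GRU with hand-set gates, one step from h=0.

        r = sig(xWr), z = sig(xWz), n = tanh(xWn), h' = (1-z) n.
        """
        Wx = Tensor(np.array([[0.5, -0.3, 0.8]]))   # [r | z | n]
        Wh = Tensor(np.zeros((1, 3)))
        b = Tensor(np.zeros(3))
        x = Tensor(np.array([[2.0]]))
        h = Tensor(np.array([[0.0]]))
        out = gru_cell(x, h, Wx, Wh, b, hidden=1)
        z = 1 / (1 + np.exp(0.6))
        expected = (1 - z) * np.tanh(1.6)
        assert out.value[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_previous_state_feeds_through_update_gate(self):
        Wx = Tensor(np.zeros((1, 3)))
        Wh = Tensor(np.zeros((1, 3)))
        b = Tensor(np.array([0.0, 10.0, 0.0]))  # z ~= 1 -> h' ~= h
        out = gru_cell(Tensor([[0.0]]), Tensor([[0.7]]), Wx, Wh, b, hidden=1)
        assert out.value[0, 0] == pytest.approx(0.7, abs=1e-4)

    def test_zero_weights_zero_hidden_states(self):
        w = {k: np.zeros_like(v) for k, v in init_weights(CFG, 0).items()}
        model = GlucoseModel(CFG, w)
        out = model.predict(np.zeros((2, 5, 3)))
        # gamma from zero weights is exactly 0; lambda/beta = softplus(0)
        np.testing.assert_allclose(out.gamma, 0.0)
        np.testing.assert_allclose(out.lam, np.log(2) + EPS)

    def test_sequence_length_preserved(self):
        from glyforecast.model import encode
        w = _wrap(init_weights(CFG, 1))
        hs, hT = encode(w, np.random.default_rng(0).normal(size=(2, 7, 3)), CFG)
        assert len(hs) == 7
        assert hs[-1] is hT

    def test_shape_mismatch_rejected(self):
        model = GlucoseModel(CFG, seed=0)
        with pytest.raises(InvalidArgumentError):
            model.predict(np.zeros((2, 5, 4)))

    def test_nan_input_rejected(self):
        model = GlucoseModel(CFG, seed=0)
        X = np.zeros((1, 5, 3))
        X[0, 2, 1] = np.nan
        with pytest.raises(InvalidArgumentError):
            model.predict(X)


class TestAttention:
    def test_weights_normalized_and_positive(self):
        rng = np.random.default_rng(3)
        hs = [Tensor(rng.normal(size=(5, 4))) for _ in range(6)]
        a = attention_weights(hs, hs[-1], Tensor(rng.normal(size=(4, 4))))
        assert (a.value > 0).all()
        np.testing.assert_allclose(a.value.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_states_uniform_weights(self):
        h = Tensor(np.ones((2, 4)))
        a = attention_weights([h, h, h], h, Tensor(np.eye(4)))
        np.testing.assert_allclose(a.value, 1.0 / 3.0)

    def test_scalar_toy_matches_softmax(self):
        hs = [Tensor([[1.0]]), Tensor([[2.0]]), Tensor([[3.0]])]
        a = attention_weights(hs, hs[-1], Tensor([[1.0]]))
        scores = np.array([3.0, 6.0, 9.0])
        expected = np.exp(scores - 9) / np.exp(scores - 9).sum()
        np.testing.assert_allclose(a.value[0], expected, atol=1e-12)

    def test_output_in_tanh_range_and_zero_for_zero_wv(self):
        rng = np.random.default_rng(4)
        hs = [Tensor(rng.normal(size=(3, 4))) for _ in range(5)]
        a = attention_weights(hs, hs[-1], Tensor(np.eye(4)))
        v = attention_output(hs, a, hs[-1], Tensor(rng.normal(size=(8, 4))))
        assert (np.abs(v.value) < 1).all()
        v0 = attention_output(hs, a, hs[-1], Tensor(np.zeros((8, 4))))
        np.testing.assert_allclose(v0.value, 0.0)

    def test_two_dim_toy_hand_computation(self):
        h1 = Tensor([[1.0, 0.0]])
        h2 = Tensor([[0.0, 1.0]])
        Wa = Tensor(np.eye(2))
        Wv = Tensor(np.array([[1.0], [0.0], [0.0], [1.0]]))  # (2*h2, v_dim=1)
        a = attention_weights([h1, h2], h2, Wa)
        # scores: h2.Wa.h1 = 0, h2.Wa.h2 = 1
        e = np.exp([0.0, 1.0])
        aw = e / e.sum()
        np.testing.assert_allclose(a.value[0], aw, atol=1e-12)
        v = attention_output([h1, h2], a, h2, Wv)
        context = aw[0] * np.array([1.0, 0.0]) + aw[1] * np.array([0.0, 1.0])
        expected = np.tanh(np.concatenate([context, [0.0, 1.0]]) @ Wv.value)
        np.testing.assert_allclose(v.value[0], expected, atol=1e-12)


class TestEvidentialHead:
    def test_softplus_mapping_at_zero(self):
        v = Tensor(np.array([[1.0]]))
        W = Tensor(np.array([[0.5, 0.0, 0.0, 0.0]]))
        b = Tensor(np.zeros(4))
        gamma, lam, alpha, beta = evidential_head(v, W, b)
        ln2 = np.log(2.0)
        assert gamma.value[0] == pytest.approx(0.5)
        assert lam.value[0] == pytest.approx(ln2, abs=1e-5)
        assert alpha.value[0] == pytest.approx(1.0 + ln2, abs=1e-5)
        assert beta.value[0] == pytest.approx(ln2, abs=1e-5)

    def test_domain_constraints_for_any_raw_values(self):
        rng = np.random.default_rng(5)
        v = Tensor(rng.normal(size=(50, 4)))
        gamma, lam, alpha, beta = evidential_head(
            v, Tensor(rng.normal(size=(4, 4)) * 5), Tensor(rng.normal(size=4) * 5))
        assert (lam.value > 0).all()
        assert (alpha.value > 1).all()
        assert (beta.value > 0).all()

    def test_uncertainty_closed_form(self):
        assert nig_uncertainty(1.0, 2.0, 2.0) == pytest.approx(np.sqrt(2.0))
        assert nig_uncertainty(2.0, 3.0, 1.0) == pytest.approx(0.5)


class TestNigLoss:
    def _loss_value(self, y, gamma, lam, alpha, beta, reg=0.0):
        return float(nig_nll_loss(np.atleast_1d(y), Tensor(np.atleast_1d(gamma)),
                                  Tensor(np.atleast_1d(lam)),
                                  Tensor(np.atleast_1d(alpha)),
                                  Tensor(np.atleast_1d(beta)), reg).value)

    def test_matches_student_t_density_oracle(self):
        """The NIG marginal is St(y; gamma, beta(1+lambda)/(lambda alpha),
        2 alpha); compare against scipy's Student-t on 100 random tuples."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            y = rng.normal()
            gamma = rng.normal()
            lam = rng.uniform(0.1, 5.0)
            alpha = rng.uniform(1.1, 6.0)
            beta = rng.uniform(0.1, 5.0)
            nll = self._loss_value(y, gamma, lam, alpha, beta)
            scale = np.sqrt(beta * (1 + lam) / (lam * alpha))
            oracle = -student_t.logpdf(y, df=2 * alpha, loc=gamma, scale=scale)
            assert nll == pytest.approx(oracle, abs=1e-8)

    def test_loss_decreases_as_gamma_approaches_target(self):
        y = 0.3
        losses = [self._loss_value(y, g, 1.0, 2.0, 1.0)
                  for g in (0.9, 0.7, 0.5, 0.35, 0.3)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_regularizer_vanishes_at_perfect_prediction(self):
        with_reg = self._loss_value(0.4, 0.4, 1.0, 2.0, 1.0, reg=0.5)
        without = self._loss_value(0.4, 0.4, 1.0, 2.0, 1.0, reg=0.0)
        assert with_reg == pytest.approx(without)

    def test_nonfinite_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            self._loss_value(np.nan, 0.0, 1.0, 2.0, 1.0)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Full forward + NIG loss gradients vs central differences, 1e-4
        relative, on every weight matrix."""
        cfg = ModelConfig(input_dim=3, hidden=5, hidden2=4, v_dim=4)
        model = GlucoseModel(cfg, seed=7)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 8, 3))
        y = rng.normal(size=6) * 0.2 + 0.5
        w = {k: v.copy() for k, v in model.weights.items()}
        _, grads = model.loss_and_grads(w, X, y)
        eps = 1e-6
        for k, arr in w.items():
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            arr[idx] += eps
            lp, _ = model.loss_and_grads(w, X, y)
            arr[idx] -= 2 * eps
            lm, _ = model.loss_and_grads(w, X, y)
            arr[idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert grads[k][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8), k

    def test_forward_deterministic(self):
        model = GlucoseModel(CFG, seed=9)
        X = np.random.default_rng(10).normal(size=(4, 6, 3))
        a = model.predict(X)
        b = model.predict(X)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.beta, b.beta)


class TestBounds:
    SCALER = TargetScaler(lo=-50.0, hi=50.0)  # scale 100, inverse y*100 - 50

    def _out(self, gamma, u):
        # lam=1, alpha=2 -> u = sqrt(beta); pick beta = u^2
        n = len(gamma)
        return NigOutput(np.asarray(gamma, float), np.ones(n),
                         np.full(n, 2.0), np.asarray(u, float) ** 2)

    def test_zero_thresholds_collapse_bounds(self):
        out = self._out([0.6, 0.4], [0.1, 0.2])
        bp = predict_with_bounds(np.array([150.0, 120.0]), out, self.SCALER,
                                 k_l=0.0, k_u=0.0)
        np.testing.assert_array_equal(bp.b_low, bp.g_hat)
        np.testing.assert_array_equal(bp.b_up, bp.g_hat)

    def test_bound_arithmetic(self):
        # m^-1(y) = 100 y - 50; gamma = 0.3 -> delta = -20; G = 150 -> 130
        out = self._out([0.3], [0.15])  # u * scale = 15
        bp = predict_with_bounds(np.array([150.0]), out, self.SCALER,
                                 k_l=1.0, k_u=2.0)
        assert bp.g_hat[0] == pytest.approx(130.0)
        assert bp.b_low[0] == pytest.approx(115.0)
        assert bp.b_up[0] == pytest.approx(160.0)

    def test_doubling_k_doubles_gap(self):
        out = self._out([0.55], [0.05])
        g = np.array([140.0])
        g1 = predict_with_bounds(g, out, self.SCALER, k_l=1.0, k_u=1.0)
        g2 = predict_with_bounds(g, out, self.SCALER, k_l=2.0, k_u=1.0)
        assert (g2.g_hat[0] - g2.b_low[0]) == pytest.approx(
            2 * (g1.g_hat[0] - g1.b_low[0]))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(11)
        out = self._out(rng.uniform(0.2, 0.8, 20), rng.uniform(0.01, 0.3, 20))
        bp = predict_with_bounds(rng.uniform(60, 250, 20), out, self.SCALER,
                                 k_l=1.5, k_u=0.5)
        assert (bp.b_low <= bp.g_hat + 1e-12).all()
        assert (bp.g_hat <= bp.b_up + 1e-12).all()

    def test_affine_inverse_mode(self):
        out = self._out([0.5], [0.1])
        bp = predict_with_bounds(np.array([150.0]), out, self.SCALER,
                                 k_l=1.0, k_u=1.0, u_inverse="affine")
        # affine m^-1(0.1) = 100*0.1 - 50 = -40 -> width is |-40|... the
        # literal inverse can produce a negative width; it is applied as-is
        assert bp.g_hat[0] == pytest.approx(150.0)
        assert bp.b_low[0] == pytest.approx(min(150.0 - 1.0 * (-40.0), 400.0))

    def test_negative_threshold_rejected(self):
        out = self._out([0.5], [0.1])
        with pytest.raises(InvalidArgumentError):
            predict_with_bounds(np.array([150.0]), out, self.SCALER, k_l=-1.0)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = GlucoseModel(CFG, seed=12,
                             target_scaler=TargetScaler(-30.0, 40.0))
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = GlucoseModel.load(path)
        X = np.random.default_rng(13).normal(size=(3, 5, 3))
        np.testing.assert_array_equal(model.predict(X).gamma,
                                      loaded.predict(X).gamma)
        assert loaded.target_scaler.lo == -30.0
        assert loaded.cfg == CFG
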