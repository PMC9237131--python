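"""Splitting, FOMAML, fine-tuning, early stopping, threshold calibration."""
import numpy as np
import pytest

from glyforecast.datatypes import InvalidArgumentError
from glyforecast.features import TargetScaler, WindowSet
from glyforecast.model import GlucoseModel, ModelConfig, NigOutput
from glyforecast.train import (DEFAULT_K_GRID, EarlyStopper, MamlConfig,
                               calibrate_thresholds,
                               chronological_split, fine_tune, maml_meta_train)

CFG = ModelConfig(input_dim=2, hidden=3, hidden2=3, v_dim=3)


def _windows(n, l=4, w=6, seed=0):
    rng = np.random.default_rng(seed)
    g = 120 + 30 * np.sin(np.arange(n + w) / 10.0)
    return WindowSet(
        X=rng.normal(size=(n, l, 2)),
        y_delta=g[w:] - g[:n],
        t_idx=np.arange(n),
        g_anchor=g[:n],
        g_target=g[w:],
        horizon_steps=w,
    )


class TestSplit:
    def test_counts_follow_50_20_rule(self):
        train, val, test = chronological_split(_windows(1000))
        assert (len(train), len(val), len(test)) == (400, 100, 500)

    def test_chronology_preserved(self):
        train, val, test = chronological_split(_windows(200))
        assert train.t_idx.max() < val.t_idx.min() < test.t_idx.min()

    def test_shuffled_input_rejected(self):
        ws = _windows(100)
        perm = np.random.default_rng(1).permutation(100)
        with pytest.raises(InvalidArgumentError, match="shuffled"):
            chronological_split(ws.subset(perm))

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chronological_split(_windows(5))

    def test_strict_mode_drops_boundary_crossers(self):
        ws = _windows(1000, l=4, w=6)
        train, val, test = chronological_split(ws, strict=True)
        test_start = test.t_idx.min()
        assert (val.t_idx + 6 < test_start).all()
        assert (test.t_idx - 3 > val.t_idx.max()).all()


class TestEarlyStopping:
    def test_walks_the_patience_rule(self):
        """val losses (5, 4, 6, 7) with patience 2 stop after the 4th epoch
        and return the 2nd epoch's weights."""
        stopper = EarlyStopper(patience=2)
        stops = []
        for epoch, loss in enumerate([5.0, 4.0, 6.0, 7.0]):
            stops.append(stopper.update(loss, {"w": np.array([float(epoch)])}))
        assert stops == [False, False, False, True]
        assert stopper.best_weights["w"][0] == 1.0

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=2)
        assert not any(stopper.update(l, {"w": np.array([l])})
                       for l in [5.0, 4.0, 3.0, 2.0])
        assert stopper.best_weights["w"][0] == 2.0

    def test_patience_one_immediate_increase_keeps_first(self):
        stopper = EarlyStopper(patience=1)
        stopper.update(1.0, {"w": np.array([0.0])})
        assert stopper.update(2.0, {"w": np.array([1.0])})
        assert stopper.best_weights["w"][0] == 0.0

    def test_invalid_patience(self):
        with pytest.raises(InvalidArgumentError):
            EarlyStopper(patience=0)


class _QuadraticModel:
    """Toy least-squares model exposing the same interface as GlucoseModel:
    loss = mean((X w - y)^2) with analytic gradients."""

    def __init__(self, dim):
        self.weights = {"w": np.zeros(dim)}

    def loss_and_grads(self, weights, X, y):
        r = X @ weights["w"] - y
        return float(np.mean(r**2)), {"w": 2 * X.T @ r / len(y)}


class TestMaml:
    def _tasks(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        tasks = []
        for slope in (1.0, -0.5, 2.0):
            X = rng.normal(size=(n, 2))
            y = X @ np.array([slope, 0.3])
            tasks.append((X, y))
        return tasks

    def test_single_task_rejected(self):
        with pytest.raises(InvalidArgumentError, match="2 task"):
            maml_meta_train(self._tasks()[:1], CFG)

    def test_first_order_update_matches_closed_form(self):
        """One outer SGD step, one inner step, full batches, quadratic loss:
        theta' = theta - a grad_s(theta); meta-grad = grad_q(theta')."""
        tasks = self._tasks(seed=2)
        maml = MamlConfig(inner_lr=0.05, outer_lr=0.1, inner_steps=1,
                          meta_batch=3, batch_size=1000, outer_steps=1,
                          outer_opt="sgd")
        model = _QuadraticModel(2)
        got = maml_meta_train(tasks, None, maml, seed=3, model=model,
                              init={"w": np.zeros(2)})
        meta_grad = np.zeros(2)
        for X, y in tasks:
            theta = np.zeros(2)
            _, g = model.loss_and_grads({"w": theta}, X, y)
            adapted = theta - 0.05 * g["w"]
            _, gq = model.loss_and_grads({"w": adapted}, X, y)
            meta_grad += gq["w"] / 3
        expected = np.zeros(2) - 0.1 * meta_grad
        np.testing.assert_allclose(got["w"], expected, atol=1e-6)

    def test_zero_inner_steps_is_pooled_gradient(self):
        """inner_steps = 0 degenerates to a plain query-gradient step."""
        tasks = self._tasks(seed=4)
        maml = MamlConfig(inner_lr=0.05, outer_lr=0.1, inner_steps=0,
                          meta_batch=3, batch_size=1000, outer_steps=1,
                          outer_opt="sgd")
        model = _QuadraticModel(2)
        got = maml_meta_train(tasks, None, maml, seed=5, model=model,
                              init={"w": np.zeros(2)})
        meta_grad = np.zeros(2)
        for X, y in tasks:
            _, g = model.loss_and_grads({"w": np.zeros(2)}, X, y)
            meta_grad += g["w"] / 3
        np.testing.assert_allclose(got["w"], -0.1 * meta_grad, atol=1e-12)

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(6)
        tasks = [(rng.normal(size=(30, 4, 2)), rng.normal(size=30) * 0.1 + 0.5)
                 for _ in range(2)]
        maml = MamlConfig(outer_steps=3, inner_steps=1, batch_size=16)
        a = maml_meta_train(tasks, CFG, maml, seed=7)
        b = maml_meta_train(tasks, CFG, maml, seed=7)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_learning_rates_validated(self):
        with pytest.raises(InvalidArgumentError):
            MamlConfig(inner_lr=0.0)


class TestFineTune:
    def _data(self, n=60, seed=8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4, 2))
        y = 0.5 + 0.1 * X[:, -1, 0]
        return X, y

    def test_zero_epochs_unchanged(self):
        X, y = self._data()
        w0 = GlucoseModel(CFG, seed=9).weights
        w1 = fine_tune(w0, CFG, X, y, max_epochs=0)
        for k in w0:
            np.testing.assert_array_equal(w0[k], w1[k])

    def test_training_reduces_loss(self):
        X, y = self._data()
        model = GlucoseModel(CFG, seed=10)
        before = model.loss(X, y)
        w = fine_tune(model.weights, CFG, X, y,
                      maml=MamlConfig(finetune_lr=5e-3, max_epochs=10,
                                      patience=10, batch_size=30), seed=1)
        assert GlucoseModel(CFG, w).loss(X, y) < before

    def test_empty_personal_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fine_tune(GlucoseModel(CFG, seed=0).weights, CFG,
                      np.empty((0, 4, 2)), np.empty(0))

    def test_checkpoint_losses_nonincreasing(self):
        """The returned weights are the best-validation checkpoint: every
        accepted improvement is monotone by construction."""
        X, y = self._data()
        log = []
        w = fine_tune(GlucoseModel(CFG, seed=11).weights, CFG, X, y,
                      maml=MamlConfig(finetune_lr=5e-3, max_epochs=8,
                                      patience=8, batch_size=30),
                      seed=2, log=log)
        losses = [e["val_loss"] for e in log]
        best_seen = np.minimum.accumulate(losses)
        final = GlucoseModel(CFG, w).loss(X, y)
        assert final == pytest.approx(best_seen[-1], rel=1e-9)


class TestCalibration:
    SCALER = TargetScaler(0.0, 1.0)  # identity: inverse(y) = y, scale = 1

    def _out(self, gamma, u):
        n = len(gamma)
        return NigOutput(np.asarray(gamma, float), np.ones(n), np.full(n, 2.0),
                         np.asarray(u, float) ** 2)

    def test_perfect_predictions_choose_k_zero(self):
        g_true = np.array([65.0, 64.0, 63.0, 120.0, 130.0, 190.0, 200.0, 110.0])
        actual_hypo = g_true < 70
        actual_hyper = g_true > 180
        out = self._out(np.zeros(8), np.full(8, 1.0))
        cal = calibrate_thresholds(g_true, out, self.SCALER,
                                   actual_hypo, actual_hyper)
        assert cal.k_l == 0.0 and cal.k_u == 0.0

    def test_constructed_set_requires_k_two(self):
        """Hypo points predicted at 75 mg/dL with u = 2.6: only k >= 2 pulls
        the lower bound below 70; non-event points never trigger."""
        n = 40
        g_hat = np.full(n, 95.0)
        u = np.full(n, 0.1)
        actual = np.zeros(n, bool)
        actual[[5, 6, 7]] = True
        g_hat[actual] = 75.0
        u[actual] = 2.6
        out = self._out(np.zeros(n), u)
        cal = calibrate_thresholds(g_hat, out, self.SCALER, actual,
                                   np.zeros(n, bool), default_k=1.0)
        assert cal.k_l == 2.0
        assert cal.warnings  # hyper class had no events -> default k

    def test_no_events_falls_back_to_default(self):
        out = self._out(np.zeros(5), np.ones(5))
        cal = calibrate_thresholds(np.full(5, 120.0), out, self.SCALER,
                                   np.zeros(5, bool), np.zeros(5, bool),
                                   default_k=1.5)
        assert cal.k_l == 1.5 and cal.k_u == 1.5
        assert len(cal.warnings) == 2

    def test_sensitivity_nondecreasing_in_k(self):
        """Raising k_l can only move points into the predicted-positive set."""
        rng = np.random.default_rng(12)
        n = 200
        g_hat = rng.uniform(55, 200, n)
        out = self._out(np.zeros(n), rng.uniform(0.5, 5.0, n))
        actual = rng.random(n) < 0.15
        prev_sens = -1.0
        from glyforecast.model import predict_with_bounds
        for k in DEFAULT_K_GRID:
            bp = predict_with_bounds(g_hat, out, self.SCALER, k_l=k, k_u=k)
            pred = bp.b_low < 70.0
            sens = (pred & actual).sum() / max(actual.sum(), 1)
            assert sens >= prev_sens - 1e-12
            prev_sens = sens


class TestLeakage:
    def test_test_set_contents_never_affect_training(self):
        """Permuting or corrupting the test windows leaves the trained
        weights byte-identical (train/test isolation)."""
        rng = np.random.default_rng(13)
        tasks = [(rng.normal(size=(40, 4, 2)), rng.normal(size=40) * 0.1 + 0.5)
                 for _ in range(2)]
        maml = MamlConfig(outer_steps=2, inner_steps=1, batch_size=16)
        ws = _windows(100)
        train, val, test = chronological_split(ws)
        w1 = maml_meta_train(tasks, CFG, maml, seed=14)
        # corrupt the test split in place
        test.X[:] = 0.0
        test.y_delta[:] = 1e9
        w2 = maml_meta_train(tasks, CFG, maml, seed=14)
        for k in w1:
            np.testing.assert_array_equal(w1[k], w2[k])
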