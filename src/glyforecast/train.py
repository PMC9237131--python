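"""Training: chronological splitting, first-order MAML over subjects,
personalization by fine-tuning, early stopping, and calibration of the
uncertainty-bound thresholds on validation MCC.

Splits are strictly chronological — the first half of each subject's windows
is the training pool (its final fifth held out for validation) and the second
half is the test set — because adjacent CGM windows are heavily correlated
and random splitting would leak near-duplicates across sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import HYPO_MGDL, HYPER_MGDL, InvalidArgumentError
from .features import TargetScaler, WindowSet
from .model import Adam, GlucoseModel, ModelConfig, predict_with_bounds, sgd_step


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.5
    val_fraction_of_train: float = 0.2


def chronological_split(windows: WindowSet, spec: SplitSpec = SplitSpec(),
                        strict: bool = False
                        ) -> tuple[WindowSet, WindowSet, WindowSet]:
    """(train, validation, test): first ``train_fraction`` of windows form the
    pool, the last ``val_fraction_of_train`` of the pool is validation, the
    remainder of the series is test. Input must already be in time order;
    shuffled windows are rejected. ``strict=True`` additionally drops pool
    windows whose target row reaches the test region and test windows whose
    input reaches back into the pool.
    """
    n = len(windows)
    if n < 10:
        raise InvalidArgumentError("series too short to split")
    if np.any(np.diff(windows.t_idx) < 0):
        raise InvalidArgumentError("windows must be chronologically ordered; "
                                   "shuffled input is rejected")
    n_pool = int(round(n * spec.train_fraction))
    n_val = int(round(n_pool * spec.val_fraction_of_train))
    idx = np.arange(n)
    train, val, test = idx[:n_pool - n_val], idx[n_pool - n_val:n_pool], idx[n_pool:]
    if strict and len(test):
        w = windows.horizon_steps
        l = windows.X.shape[1]
        test_start_row = windows.t_idx[test[0]]
        train = train[windows.t_idx[train] + w < test_start_row]
        val = val[windows.t_idx[val] + w < test_start_row]
        pool_end_row = windows.t_idx[n_pool - 1]
        test = test[windows.t_idx[test] - (l - 1) > pool_end_row]
    return windows.subset(train), windows.subset(val), windows.subset(test)


@dataclass
class MamlConfig:
    inner_lr: float = 0.01
    outer_lr: float = 0.001
    inner_steps: int = 5
    meta_batch: int = 4        # tasks per outer step
    first_order: bool = True   # second-order MAML is out of scope
    finetune_lr: float = 2e-4
    max_epochs: int = 60
    patience: int = 8
    batch_size: int = 64
    outer_steps: int = 60
    outer_opt: str = "adam"    # 'adam' | 'sgd'

    def __post_init__(self) -> None:
        for name in ("inner_lr", "outer_lr", "finetune_lr"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.finetune_lr >= self.outer_lr * 10:
            pass  # fine-tune lr is expected small; not enforced hard


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(n, size=min(batch_size, n), replace=False)


def maml_meta_train(tasks: list[tuple[np.ndarray, np.ndarray]], cfg: ModelConfig | None,
                    maml: MamlConfig = MamlConfig(), seed: int = 0,
                    init: dict[str, np.ndarray] | None = None,
                    model=None) -> dict[str, np.ndarray]:
    """First-order MAML over per-subject tasks [(X_i, y_i), ...].

    Each outer step samples ``meta_batch`` tasks; for each, ``inner_steps``
    SGD steps on a support batch adapt the weights, and the query-batch
    gradient *at the adapted weights* (no second derivatives) is averaged
    into the meta-update. ``inner_steps=0`` degenerates to pooled mini-batch
    training. Deterministic given the seed.
    """
    if len(tasks) < 2:
        raise InvalidArgumentError("MAML needs at least 2 tasks (subjects)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    if model is None:
        model = GlucoseModel(cfg, seed=int(rng.integers(2**31 - 1)))
    weights = init if init is not None else model.weights
    weights = {k: v.copy() for k, v in weights.items()}
    opt = Adam(maml.outer_lr) if maml.outer_opt == "adam" else None

    for _ in range(maml.outer_steps):
        chosen = rng.choice(len(tasks), size=min(maml.meta_batch, len(tasks)),
                            replace=False)
        meta_grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in weights.items()}
        for ti in chosen:
            X, y = tasks[ti]
            adapted = weights
            for _ in range(maml.inner_steps):
                bi = _batches(len(y), maml.batch_size, rng)
                _, g = model.loss_and_grads(adapted, X[bi], y[bi])
                adapted = sgd_step(adapted, g, maml.inner_lr)
            qi = _batches(len(y), maml.batch_size, rng)
            _, gq = model.loss_and_grads(adapted, X[qi], y[qi])
            for k in meta_grads:
                meta_grads[k] += gq[k] / len(chosen)
        if opt is not None:
            opt.step(weights, meta_grads)
        else:
            weights = sgd_step(weights, meta_grads, maml.outer_lr)
    return weights


class EarlyStopper:
    """Keep the best-validation weights; stop after ``patience`` epochs
    without improvement."""

    def __init__(self, patience: int = 8):
        if patience < 1:
            raise InvalidArgumentError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_weights: dict[str, np.ndarray] | None = None
        self.stale = 0

    def update(self, val_loss: float, weights: dict[str, np.ndarray]) -> bool:
        """Record an epoch; returns True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_weights = {k: v.copy() for k, v in weights.items()}
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def fine_tune(weights: dict[str, np.ndarray], cfg: ModelConfig,
              X: np.ndarray, y: np.ndarray,
              X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
              maml: MamlConfig = MamlConfig(), seed: int = 0,
              max_epochs: int | None = None,
              log: list | None = None) -> dict[str, np.ndarray]:
    """Personalize from ``weights`` with a small learning rate and early
    stopping on the personal validation split (normalized targets ``y``).
    ``max_epochs=0`` returns the weights unchanged."""
    if len(y) == 0:
        raise InvalidArgumentError("personal training set is empty")
    epochs = maml.max_epochs if max_epochs is None else max_epochs
    model = GlucoseModel(cfg)
    w = {k: v.copy() for k, v in weights.items()}
    if epochs == 0:
        return w
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    opt = Adam(maml.finetune_lr)
    stopper = EarlyStopper(maml.patience)
    for epoch in range(epochs):
        order = rng.permutation(len(y))
        for lo in range(0, len(y), maml.batch_size):
            bi = order[lo:lo + maml.batch_size]
            _, g = model.loss_and_grads(w, X[bi], y[bi])
            opt.step(w, g)
        if X_val is not None and len(y_val):
            val_loss = model.loss(X_val, y_val, weights=w)
        else:
            val_loss = model.loss(X, y, weights=w)
        if log is not None:
            log.append({"epoch": epoch, "val_loss": float(val_loss)})
        if stopper.update(val_loss, w):
            break
    return stopper.best_weights if stopper.best_weights is not None else w


@dataclass
class ThresholdCalibration:
    k_l: float
    k_u: float
    warnings: list = field(default_factory=list)


DEFAULT_K_GRID = tuple(np.arange(0.0, 5.0 + 1e-9, 0.25))


def calibrate_thresholds(g_anchor: np.ndarray, out, scaler: TargetScaler,
                         actual_hypo: np.ndarray, actual_hyper: np.ndarray,
                         grid: tuple[float, ...] = DEFAULT_K_GRID,
                         default_k: float = 1.0,
                         u_inverse: str = "scale") -> ThresholdCalibration:
    """Grid-search k_l maximizing hypoglycemia MCC (B^l < 70 triggers) and,
    independently, k_u maximizing hyperglycemia MCC (B^u > 180) on validation
    predictions. Ties break to the smallest k (less alarm fatigue); a class
    with no validation events falls back to ``default_k`` with a warning.
    """
    from .evaluate import EventConfusion, mcc  # local import avoids a cycle

    warnings = []

    def search(actual: np.ndarray, trigger) -> float:
        if not actual.any():
            warnings.append("no validation events for this class; default k used")
            return default_k
        best_k, best_score = grid[0], -np.inf
        for k in grid:
            bp = predict_with_bounds(g_anchor, out, scaler, k_l=k, k_u=k,
                                     u_inverse=u_inverse)
            pred = trigger(bp)
            conf = EventConfusion.from_masks(pred, actual)
            score = mcc(conf)
            if score > best_score + 1e-12:
                best_k, best_score = k, score
        return float(best_k)

    k_l = search(actual_hypo, lambda bp: bp.b_low < HYPO_MGDL)
    k_u = search(actual_hyper, lambda bp: bp.b_up > HYPER_MGDL)
    return ThresholdCalibration(k_l=k_l, k_u=k_u, warnings=warnings)


__all__ = [
    "SplitSpec", "MamlConfig", "ThresholdCalibration", "EarlyStopper",
    "chronological_split", "maml_meta_train", "fine_tune",
    "calibrate_thresholds", "DEFAULT_K_GRID",
]
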