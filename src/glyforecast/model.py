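"""Attention-based bidirectional GRU with an evidential output head.

The encoder stacks a bidirectional GRU over the input window with a second,
unidirectional GRU on the merged forward/backward states. A multiplicative
(Luong-style) attention,

    a_t = softmax_t(h_T^T W_a h_t),    v = tanh(W_v [sum_t a_t h_t ; h_T]),

pools the hidden states, and a four-neuron dense layer maps v to the
parameters (gamma, lambda, alpha, beta) of a normal-inverse-gamma prior over
the predictive mean and variance: mu ~ N(gamma, sigma^2/lambda),
sigma^2 ~ InvGamma(alpha, beta). The point prediction is gamma, the epistemic
uncertainty u = sqrt(beta / (lambda (alpha - 1))), and the marginal
likelihood of a target is Student-t, giving the training loss

    -log St(y; gamma, beta (1 + lambda) / (lambda alpha), 2 alpha)
    + reg_coef |y - gamma| (2 lambda + alpha).

Softplus activations (with a +1 shift for alpha) enforce the NIG domain
lambda > 0, alpha > 1, beta > 0 by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .datatypes import InvalidArgumentError
from .features import TargetScaler

EPS = 1e-6


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    input_dim: int
    hidden: int = 32        # units per GRU direction
    hidden2: int = 32       # second (unidirectional) GRU
    v_dim: int = 32         # attention output vector
    reg_coef: float = 0.01  # evidence regularizer


def init_weights(cfg: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Glorot-uniform initial weights keyed by layer name."""
    rng = np.random.default_rng(seed)

    def glorot(n_in, n_out):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, (n_in, n_out))

    c, h, h2, vd = cfg.input_dim, cfg.hidden, cfg.hidden2, cfg.v_dim
    w = {}
    for d in ("fw", "bw"):
        w[f"{d}_Wx"] = glorot(c, 3 * h)
        w[f"{d}_Wh"] = glorot(h, 3 * h)
        w[f"{d}_b"] = np.zeros(3 * h)
    w["g2_Wx"] = glorot(2 * h, 3 * h2)
    w["g2_Wh"] = glorot(h2, 3 * h2)
    w["g2_b"] = np.zeros(3 * h2)
    w["attn_Wa"] = glorot(h2, h2)
    w["attn_Wv"] = glorot(2 * h2, vd)
    w["head_W"] = glorot(vd, 4)
    w["head_b"] = np.zeros(4)
    return w


def _wrap(weights: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v) for k, v in weights.items()}


# ---------------------------------------------------------------------------
# Forward pass (functional: weights in, tensors out)
# ---------------------------------------------------------------------------

def gru_cell(x: Tensor, h: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
             hidden: int) -> Tensor:
    """Standard gated-recurrent update with reset (r) and update (z) gates:
    h' = (1 - z) * n + z * h, n = tanh(W_n x + r * (U_n h) + b_n)."""
    gx = x @ Wx + b
    gh = h @ Wh
    r = ad.sigmoid(gx[:, 0:hidden] + gh[:, 0:hidden])
    z = ad.sigmoid(gx[:, hidden:2 * hidden] + gh[:, hidden:2 * hidden])
    n = ad.tanh(gx[:, 2 * hidden:] + r * gh[:, 2 * hidden:])
    return (1.0 - z) * n + z * h


def _gru_layer(xs: list[Tensor], Wx: Tensor, Wh: Tensor, b: Tensor,
               hidden: int, batch: int, reverse: bool = False) -> list[Tensor]:
    h = ad.constant(np.zeros((batch, hidden)))
    order = reversed(xs) if reverse else xs
    states = []
    for x in order:
        h = gru_cell(x, h, Wx, Wh, b, hidden)
        states.append(h)
    return states[::-1] if reverse else states


def encode(weights_t: dict[str, Tensor], X: np.ndarray, cfg: ModelConfig
           ) -> tuple[list[Tensor], Tensor]:
    """Hidden states h_1..h_T of the second GRU layer, plus the final h_T.
    X has shape (batch, l, c)."""
    if X.ndim != 3 or X.shape[2] != cfg.input_dim:
        raise InvalidArgumentError(
            f"input shape {X.shape} does not match input_dim={cfg.input_dim}")
    if np.isnan(X).any():
        raise InvalidArgumentError("model input contains missing values")
    batch, length, _ = X.shape
    xs = [ad.constant(X[:, t, :]) for t in range(length)]
    fw = _gru_layer(xs, weights_t["fw_Wx"], weights_t["fw_Wh"], weights_t["fw_b"],
                    cfg.hidden, batch)
    bw = _gru_layer(xs, weights_t["bw_Wx"], weights_t["bw_Wh"], weights_t["bw_b"],
                    cfg.hidden, batch, reverse=True)
    merged = [ad.concat([b_, f_], axis=1) for f_, b_ in zip(fw, bw)]  # [backward; forward]
    hs = _gru_layer(merged, weights_t["g2_Wx"], weights_t["g2_Wh"], weights_t["g2_b"],
                    cfg.hidden2, batch)
    return hs, hs[-1]


def attention_weights(hs: list[Tensor], h_T: Tensor, W_a: Tensor) -> Tensor:
    """a_t = softmax_t(h_T^T W_a h_t); shape (batch, T)."""
    proj = h_T @ W_a  # (batch, h2): rows h_T^T W_a
    scores = [(proj * h).sum(axis=1) for h in hs]
    return ad.softmax(ad.stack(scores, axis=1), axis=1)


def attention_output(hs: list[Tensor], a: Tensor, h_T: Tensor, W_v: Tensor) -> Tensor:
    """v = tanh(W_v [sum_t a_t h_t ; h_T])."""
    context = None
    for t, h in enumerate(hs):
        term = a[:, t:t + 1] * h
        context = term if context is None else context + term
    return ad.tanh(ad.concat([context, h_T], axis=1) @ W_v)


def evidential_head(v: Tensor, W: Tensor, b: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Affine layer to 4 raw outputs; softplus maps onto the NIG domain."""
    raw = v @ W + b
    gamma = raw[:, 0]
    lam = ad.softplus(raw[:, 1]) + EPS
    alpha = ad.softplus(raw[:, 2]) + (1.0 + EPS)
    beta = ad.softplus(raw[:, 3]) + EPS
    return gamma, lam, alpha, beta


def forward(weights_t: dict[str, Tensor], X: np.ndarray, cfg: ModelConfig
            ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    hs, h_T = encode(weights_t, X, cfg)
    a = attention_weights(hs, h_T, weights_t["attn_Wa"])
    v = attention_output(hs, a, h_T, weights_t["attn_Wv"])
    return evidential_head(v, weights_t["head_W"], weights_t["head_b"])


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def nig_nll_loss(y: np.ndarray, gamma: Tensor, lam: Tensor, alpha: Tensor,
                 beta: Tensor, reg_coef: float = 0.01) -> Tensor:
    """Mean Student-t NLL of the NIG marginal plus the evidence regularizer."""
    y = np.asarray(y, float)
    if not np.isfinite(y).all():
        raise InvalidArgumentError("targets must be finite")
    yt = ad.constant(y)
    nu = 2.0 * alpha
    s2 = beta * (1.0 + lam) / (lam * alpha)   # Student-t scale^2
    resid2 = (yt - gamma) ** 2
    logpdf = (ad.gammaln((nu + 1.0) * 0.5) - ad.gammaln(nu * 0.5)
              - 0.5 * ad.log(nu * np.pi * s2)
              - (nu + 1.0) * 0.5 * ad.log(1.0 + resid2 / (nu * s2)))
    reg = ad.absolute(yt - gamma) * (2.0 * lam + alpha)
    return (-logpdf + reg_coef * reg).mean()


def nig_uncertainty(lam: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Epistemic uncertainty u = sqrt(beta / (lambda (alpha - 1)))."""
    lam = np.maximum(np.asarray(lam, float), EPS)
    am1 = np.maximum(np.asarray(alpha, float) - 1.0, EPS)
    beta = np.maximum(np.asarray(beta, float), EPS)
    return np.sqrt(beta / (lam * am1))


# ---------------------------------------------------------------------------
# Prediction containers
# ---------------------------------------------------------------------------

@dataclass
class NigOutput:
    """Per-window evidential parameters (normalized glucose-change units)."""

    gamma: np.ndarray
    lam: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    @property
    def y_hat(self) -> np.ndarray:
        return self.gamma

    @property
    def u(self) -> np.ndarray:
        return nig_uncertainty(self.lam, self.alpha, self.beta)


@dataclass
class BoundedPrediction:
    """Glucose prediction with uncertainty bounds, all in mg/dL."""

    g_hat: np.ndarray
    b_low: np.ndarray
    b_up: np.ndarray
    u: np.ndarray
    horizon_steps: int = 0


def predict_with_bounds(g_anchor: np.ndarray, out: NigOutput, scaler: TargetScaler,
                        k_l: float = 1.0, k_u: float = 1.0,
                        horizon_steps: int = 0, u_inverse: str = "scale",
                        clamp: tuple[float, float] = (40.0, 400.0)) -> BoundedPrediction:
    """G_hat = G_t + m^-1(y_hat); bounds G_hat -+ k * m^-1(u).

    ``u_inverse='scale'`` de-normalizes the uncertainty with the training
    (max - min) of the target only — an uncertainty is a scale, not a
    location. ``'affine'`` applies the literal affine inverse instead.
    """
    if k_l < 0 or k_u < 0:
        raise InvalidArgumentError("bound thresholds must be nonnegative")
    g_hat = np.asarray(g_anchor, float) + scaler.inverse(out.y_hat)
    if u_inverse == "scale":
        width = out.u * scaler.scale
    elif u_inverse == "affine":
        width = scaler.inverse(out.u)
    else:
        raise InvalidArgumentError("u_inverse must be 'scale' or 'affine'")
    b_low = g_hat - k_l * width
    b_up = g_hat + k_u * width
    lo, hi = clamp
    return BoundedPrediction(
        g_hat=np.clip(g_hat, lo, hi),
        b_low=np.clip(b_low, lo, hi),
        b_up=np.clip(b_up, lo, hi),
        u=out.u,
        horizon_steps=horizon_steps,
    )


# ---------------------------------------------------------------------------
# Model object + optimizer
# ---------------------------------------------------------------------------

class GlucoseModel:
    """Stateful wrapper: config + weights + target scaler."""

    def __init__(self, cfg: ModelConfig, weights: dict[str, np.ndarray] | None = None,
                 seed: int = 0, target_scaler: TargetScaler | None = None):
        self.cfg = cfg
        self.weights = weights if weights is not None else init_weights(cfg, seed)
        self.target_scaler = target_scaler

    def copy(self) -> "GlucoseModel":
        return GlucoseModel(self.cfg, {k: v.copy() for k, v in self.weights.items()},
                            target_scaler=self.target_scaler)

    def predict(self, X: np.ndarray, weights: dict[str, np.ndarray] | None = None
                ) -> NigOutput:
        w = _wrap(weights if weights is not None else self.weights)
        gamma, lam, alpha, beta = forward(w, X, self.cfg)
        return NigOutput(gamma.value, lam.value, alpha.value, beta.value)

    def loss(self, X: np.ndarray, y: np.ndarray,
             weights: dict[str, np.ndarray] | None = None) -> float:
        w = _wrap(weights if weights is not None else self.weights)
        gamma, lam, alpha, beta = forward(w, X, self.cfg)
        return float(nig_nll_loss(y, gamma, lam, alpha, beta, self.cfg.reg_coef).value)

    def loss_and_grads(self, weights: dict[str, np.ndarray], X: np.ndarray,
                       y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        w = _wrap(weights)
        gamma, lam, alpha, beta = forward(w, X, self.cfg)
        loss = nig_nll_loss(y, gamma, lam, alpha, beta, self.cfg.reg_coef)
        loss.backward()
        grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.value))
                 for k, t in w.items()}
        return float(loss.value), grads

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        meta = dict(format_version=1, input_dim=self.cfg.input_dim,
                    hidden=self.cfg.hidden, hidden2=self.cfg.hidden2,
                    v_dim=self.cfg.v_dim, reg_coef=self.cfg.reg_coef,
                    target_lo=self.target_scaler.lo if self.target_scaler else np.nan,
                    target_hi=self.target_scaler.hi if self.target_scaler else np.nan)
        np.savez(path, __meta__=np.array([list(meta.items())], dtype=object),
                 **self.weights)

    @classmethod
    def load(cls, path) -> "GlucoseModel":
        data = np.load(path, allow_pickle=True)
        meta = dict(data["__meta__"][0])
        if int(meta["format_version"]) != 1:
            raise InvalidArgumentError("unknown checkpoint format version")
        cfg = ModelConfig(input_dim=int(meta["input_dim"]), hidden=int(meta["hidden"]),
                          hidden2=int(meta["hidden2"]), v_dim=int(meta["v_dim"]),
                          reg_coef=float(meta["reg_coef"]))
        weights = {k: data[k] for k in data.files if k != "__meta__"}
        scaler = None
        if np.isfinite(float(meta["target_lo"])):
            scaler = TargetScaler(float(meta["target_lo"]), float(meta["target_hi"]))
        return cls(cfg, weights, target_scaler=scaler)


class Adam:
    """Plain Adam on a dict of weight arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            weights[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sgd_step(weights: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> dict[str, np.ndarray]:
    """Functional SGD step (returns new dict; used by the inner MAML loop)."""
    return {k: weights[k] - lr * grads[k] for k in weights}


__all__ = [
    "ModelConfig", "GlucoseModel", "NigOutput", "BoundedPrediction", "Adam",
    "init_weights", "encode", "gru_cell", "attention_weights", "attention_output",
    "evidential_head", "forward", "nig_nll_loss", "nig_uncertainty",
    "predict_with_bounds", "sgd_step", "EPS",
]
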