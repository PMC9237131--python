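"""Glycemic-event extraction, bound-based event prediction, and metrics:
RMSE, glucose-specific RMSE, MAE, MAPE, time lag, classification scores
(accuracy/sensitivity/specificity/precision/MCC) and mean deviation of
missed events.

An adverse glycemic event is at least three consecutive CGM readings
(>= 15 min) below 70 mg/dL (hypoglycemia) or above 180 mg/dL
(hyperglycemia); a missing reading breaks consecutiveness. Confusion counts
are tallied per grid point: at time t the classifier is positive when the
lower bound B^l_{t+w} drops below 70 (hypo) or the upper bound B^u_{t+w}
exceeds 180 (hyper), and the truth is positive when t+w lies inside a true
event. gRMSE multiplies each squared error by a penalty P >= 1 that
emphasizes clinically dangerous mistakes — overestimating low glucose and
underestimating high glucose.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CgmSeries, HYPER_MGDL, HYPO_MGDL, InvalidArgumentError

MIN_EVENT_READINGS = 3


@dataclass
class GlycemicEvent:
    type: str                 # 'hypo' | 'hyper'
    start_idx: int
    end_idx: int              # inclusive
    start: pd.Timestamp
    end: pd.Timestamp
    readings: np.ndarray      # mg/dL

    @property
    def n_readings(self) -> int:
        return self.end_idx - self.start_idx + 1


def _qualifies(glucose: np.ndarray, kind: str) -> np.ndarray:
    if kind == "hypo":
        return glucose < HYPO_MGDL
    if kind == "hyper":
        return glucose > HYPER_MGDL
    raise InvalidArgumentError("event type must be 'hypo' or 'hyper'")


def extract_events(cgm: CgmSeries, kind: str) -> list[GlycemicEvent]:
    """Maximal runs of >= 3 consecutive qualifying readings; NaN (missing)
    readings break a run."""
    g = cgm.glucose
    q = _qualifies(g, kind) & ~np.isnan(g)
    events = []
    i, n = 0, len(q)
    while i < n:
        if not q[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and q[j + 1]:
            j += 1
        if j - i + 1 >= MIN_EVENT_READINGS:
            events.append(GlycemicEvent(kind, i, j, cgm.times[i], cgm.times[j],
                                        g[i:j + 1].copy()))
        i = j + 1
    return events


def event_membership(cgm: CgmSeries, kind: str) -> np.ndarray:
    """Boolean per grid point: inside a true event of this class."""
    mask = np.zeros(len(cgm), bool)
    for ev in extract_events(cgm, kind):
        mask[ev.start_idx:ev.end_idx + 1] = True
    return mask


@dataclass
class EventConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_masks(cls, predicted: np.ndarray, actual: np.ndarray,
                   evaluable: np.ndarray | None = None) -> "EventConfusion":
        p = np.asarray(predicted, bool)
        a = np.asarray(actual, bool)
        if p.shape != a.shape:
            raise InvalidArgumentError("prediction/truth grids do not match")
        if evaluable is not None:
            p, a = p[evaluable], a[evaluable]
        return cls(tp=int((p & a).sum()), fp=int((p & ~a).sum()),
                   fn=int((~p & a).sum()), tn=int((~p & ~a).sum()))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_points(b_low: np.ndarray, b_up: np.ndarray, actual: np.ndarray,
                    kind: str, evaluable: np.ndarray | None = None
                    ) -> EventConfusion:
    """Grid-point confusion for one class and horizon. ``actual[i]`` says
    whether the target time of prediction i lies inside a true event."""
    if kind == "hypo":
        pred = np.asarray(b_low, float) < HYPO_MGDL
    elif kind == "hyper":
        pred = np.asarray(b_up, float) > HYPER_MGDL
    else:
        raise InvalidArgumentError("event type must be 'hypo' or 'hyper'")
    return EventConfusion.from_masks(pred, actual, evaluable)


def mcc(conf: EventConfusion) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal
    count is zero."""
    tp, fp, fn, tn = conf.tp, conf.fp, conf.fn, conf.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def classification_scores(conf: EventConfusion) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/precision in percent, plus MCC."""
    def safe(num, den):
        return float(num / den * 100.0) if den > 0 else float("nan")
    return {
        "accuracy": safe(conf.tp + conf.tn, conf.n),
        "sensitivity": safe(conf.tp, conf.tp + conf.fn),
        "specificity": safe(conf.tn, conf.tn + conf.fp),
        "precision": safe(conf.tp, conf.tp + conf.fp),
        "mcc": mcc(conf),
    }


# ---------------------------------------------------------------------------
# Pointwise regression metrics
# ---------------------------------------------------------------------------

def pointwise_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """RMSE and MAE in mg/dL, MAPE in percent."""
    yt, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    if yt.shape != yp.shape:
        raise InvalidArgumentError("length mismatch")
    if yt.size == 0:
        raise InvalidArgumentError("need at least one point")
    err = yt - yp
    nz = yt != 0
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "mape": float(np.mean(np.abs(err[nz] / yt[nz])) * 100.0),
    }


@dataclass(frozen=True)
class GrmseParams:
    """Penalty constants: alpha (height), beta (glucose-sigmoid width),
    gamma (error-sigmoid width), T (glucose threshold) for the low (L) and
    high (H) branches, glucose units mg/dL."""

    alpha_l: float = 1.5
    beta_l: float = 30.0
    gamma_l: float = 10.0
    t_l: float = 85.0
    alpha_h: float = 1.0
    beta_h: float = 100.0
    gamma_h: float = 20.0
    t_h: float = 155.0


def _sigma_rise(x: np.ndarray, threshold: float, width: float) -> np.ndarray:
    """Logistic rising from 0 to 1 around ``threshold`` over ~``width``."""
    return 1.0 / (1.0 + np.exp(-4.0 * (x - threshold) / width))


def grmse_penalty(g_true: np.ndarray, g_pred: np.ndarray,
                  params: GrmseParams = GrmseParams()) -> np.ndarray:
    """P(G, G_hat) >= 1: the low branch activates when G is below T_L *and*
    the prediction overestimates (G_hat - G > 0); the high branch when G is
    above T_H and the prediction underestimates."""
    g, gh = np.asarray(g_true, float), np.asarray(g_pred, float)
    diff = gh - g
    low = (1.0 - _sigma_rise(g, params.t_l, params.beta_l)) \
        * _sigma_rise(diff, 0.0, params.gamma_l)
    high = _sigma_rise(g, params.t_h, params.beta_h) \
        * (1.0 - _sigma_rise(diff, 0.0, params.gamma_h))
    return 1.0 + params.alpha_l * low + params.alpha_h * high


def grmse(y_true: np.ndarray, y_pred: np.ndarray,
          params: GrmseParams = GrmseParams()) -> float:
    """sqrt(mean(P * squared error)); always >= RMSE since P >= 1."""
    yt, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    if yt.shape != yp.shape:
        raise InvalidArgumentError("length mismatch")
    if yt.size == 0:
        raise InvalidArgumentError("need at least one point")
    p = grmse_penalty(yt, yp, params)
    return float(np.sqrt(np.mean(p * (yt - yp) ** 2)))


def time_lag(y_true: np.ndarray, y_pred: np.ndarray, resolution_min: float = 5.0,
             max_shift: int = 12, min_len: int = 50) -> float:
    """Cross-correlation delay of the prediction behind the truth, in
    minutes: the nonnegative shift maximizing corr(pred[s:], true[:-s])."""
    yt, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    if yt.size != yp.size or yt.size < min_len:
        raise InvalidArgumentError(f"need equal-length series of >= {min_len} points")
    best_s, best_c = 0, -np.inf
    for s in range(0, max_shift + 1):
        a = yp[s:] if s else yp
        b = yt[:yt.size - s] if s else yt
        if a.std() == 0 or b.std() == 0:
            c = -np.inf if s else np.inf  # constant series: zero lag
        else:
            c = float(np.corrcoef(a, b)[0, 1])
        if c > best_c:
            best_s, best_c = s, c
    return best_s * resolution_min


def missed_event_deviation(events: list[GlycemicEvent], predicted_positive: np.ndarray,
                           g_hat_by_idx: dict[int, float] | np.ndarray,
                           g_true: np.ndarray) -> float | None:
    """MAE of predictions inside events none of whose points was predicted
    positive; None (absent, not 0) when every event was at least partly
    detected. ``predicted_positive`` is indexed by grid point."""
    devs = []
    pred = np.asarray(predicted_positive, bool)
    for ev in events:
        span = np.arange(ev.start_idx, ev.end_idx + 1)
        span = span[span < len(pred)]
        if span.size == 0 or pred[span].any():
            continue
        for i in span:
            gh = g_hat_by_idx[i] if not isinstance(g_hat_by_idx, dict) else g_hat_by_idx.get(i)
            if gh is not None and np.isfinite(gh) and np.isfinite(g_true[i]):
                devs.append(abs(gh - g_true[i]))
    return float(np.mean(devs)) if devs else None


# ---------------------------------------------------------------------------
# Subject / cohort reports
# ---------------------------------------------------------------------------

@dataclass
class HorizonReport:
    horizon_min: float
    regression: dict[str, float]
    hypo: dict[str, float]
    hyper: dict[str, float]
    hypo_confusion: EventConfusion
    hyper_confusion: EventConfusion
    md_hypo: float | None
    md_hyper: float | None

    def to_dict(self) -> dict:
        return {
            "horizon_min": self.horizon_min,
            "regression": self.regression,
            "hypo": self.hypo, "hyper": self.hyper,
            "hypo_confusion": vars(self.hypo_confusion),
            "hyper_confusion": vars(self.hyper_confusion),
            "md_hypo": self.md_hypo, "md_hyper": self.md_hyper,
        }


def evaluate_subject(cgm: CgmSeries, t_idx: np.ndarray, horizon_steps: int,
                     g_hat: np.ndarray, b_low: np.ndarray, b_up: np.ndarray,
                     resolution_min: float = 5.0) -> HorizonReport:
    """All metrics for one subject and one horizon. ``t_idx`` are the anchor
    grid indices of the predictions; targets are at ``t_idx + horizon_steps``
    and are restricted to observed (non-interpolated) readings."""
    tgt = t_idx + horizon_steps
    g_true = cgm.glucose[tgt]
    ok = np.isfinite(g_true)
    tgt, g_true = tgt[ok], g_true[ok]
    g_hat, b_low, b_up = g_hat[ok], b_low[ok], b_up[ok]

    regression = pointwise_metrics(g_true, g_hat)
    regression["grmse"] = grmse(g_true, g_hat)
    try:
        regression["time_lag_min"] = time_lag(g_true, g_hat, resolution_min)
    except InvalidArgumentError:
        regression["time_lag_min"] = float("nan")

    report = {}
    mds = {}
    confs = {}
    for kind, bound in (("hypo", b_low), ("hyper", b_up)):
        actual = event_membership(cgm, kind)[tgt]
        conf = classify_points(b_low, b_up, actual, kind)
        confs[kind] = conf
        report[kind] = classification_scores(conf)
        # event-level MD: predictions mapped back onto the grid
        pred_grid = np.zeros(len(cgm), bool)
        ghat_grid = np.full(len(cgm), np.nan)
        pred = bound < HYPO_MGDL if kind == "hypo" else bound > HYPER_MGDL
        pred_grid[tgt] = pred
        ghat_grid[tgt] = g_hat
        events = [ev for ev in extract_events(cgm, kind)]
        mds[kind] = missed_event_deviation(events, pred_grid, ghat_grid, cgm.glucose)

    return HorizonReport(
        horizon_min=horizon_steps * resolution_min,
        regression=regression, hypo=report["hypo"], hyper=report["hyper"],
        hypo_confusion=confs["hypo"], hyper_confusion=confs["hyper"],
        md_hypo=mds["hypo"], md_hyper=mds["hyper"],
    )


def aggregate_cohort(values: list[float]) -> dict[str, float]:
    """Mean +- SD across subjects (the cohort-table convention)."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], float)
    if arr.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size)}


__all__ = [
    "GlycemicEvent", "EventConfusion", "GrmseParams", "HorizonReport",
    "extract_events", "event_membership", "classify_points", "mcc",
    "classification_scores", "pointwise_metrics", "grmse", "grmse_penalty",
    "time_lag", "missed_event_deviation", "evaluate_subject", "aggregate_cohort",
    "MIN_EVENT_READINGS",
]
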