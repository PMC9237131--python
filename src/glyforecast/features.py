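"""Feature engineering: daily entries to insulin/carbohydrate on board,
assembly of the aligned multivariate matrix, gap handling, min-max
normalization, collinearity-group feature selection, and windowing into model
inputs and glucose-change targets.

The whole pipeline is causal: interior gaps are linearly interpolated between
flanking observations, tail gaps are carried forward (never backward), and
every window's features end at its anchor time t, so truncating the series
after t can never change anything computed at or before t.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CgmSeries, EventLog, InvalidArgumentError

CORE_FEATURES = ("glucose", "cob", "iob", "time_index")
#: Collinearity groups: variants of the same measurement; exactly one of each
#: wristband group enters the model (mirrors the published final input set).
IBI_GROUP = ("ibi_mean", "sdnn", "rmssd", "lf", "hf", "lf_hf")
EDA_GROUP = ("scl_mean", "scr_mean", "scr_count")
DEFAULT_SELECTED = CORE_FEATURES + ("ibi_mean", "scr_mean")

DEFAULT_HORIZONS = (3, 6, 9, 12)  # grid steps = 15, 30, 45, 60 min


# ---------------------------------------------------------------------------
# On-board models
# ---------------------------------------------------------------------------

def iob_remaining_fraction(elapsed_h: np.ndarray | float, duration_h: float = 4.0,
                           knots: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 0.9))
                           ) -> np.ndarray:
    """Fraction of a bolus still active after ``elapsed_h`` hours.

    Piecewise-linear, two slopes by default: slow decay to 90% over the first
    hour, then linear to zero at ``duration_h`` (insulin acts for four hours;
    the exact curve varies by pump, hence config-exposed knots).
    """
    xs = [k[0] for k in knots] + [duration_h]
    ys = [k[1] for k in knots] + [0.0]
    e = np.asarray(elapsed_h, dtype=float)
    out = np.interp(e, xs, ys)
    return np.where(e < 0, 0.0, np.where(e >= duration_h, 0.0, out))


def insulin_on_board(boluses: EventLog | pd.DataFrame, t: pd.Timestamp,
                     duration_h: float = 4.0,
                     knots: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 0.9))
                     ) -> float:
    """Units of insulin still active at time t, summed over past boluses."""
    df = boluses.boluses if isinstance(boluses, EventLog) else boluses
    if len(df) == 0:
        return 0.0
    if (df["value"] < 0).any():
        raise InvalidArgumentError("bolus doses must be nonnegative")
    elapsed_h = (t - df["timestamp"]).dt.total_seconds().to_numpy() / 3600.0
    frac = iob_remaining_fraction(elapsed_h, duration_h, knots)
    return float(np.sum(df["value"].to_numpy() * frac))


def carbohydrate_on_board(meals: EventLog | pd.DataFrame, t: pd.Timestamp,
                          rate_g_per_min: float = 2.5, delay_min: float = 15.0) -> float:
    """Grams of unabsorbed carbohydrate at time t.

    Each meal of C grams sits unabsorbed for ``delay_min`` minutes, then
    absorbs at a constant ``rate_g_per_min`` until exhausted.
    """
    df = meals.meals if isinstance(meals, EventLog) else meals
    if len(df) == 0:
        return 0.0
    if (df["value"] < 0).any():
        raise InvalidArgumentError("carbohydrate amounts must be nonnegative")
    elapsed_min = (t - df["timestamp"]).dt.total_seconds().to_numpy() / 60.0
    c = df["value"].to_numpy()
    absorbed = np.clip((elapsed_min - delay_min) * rate_g_per_min, 0.0, None)
    cob = np.where(elapsed_min < 0, 0.0, np.clip(c - absorbed, 0.0, None))
    return float(cob.sum())


def onboard_series(events: EventLog, times: pd.DatetimeIndex,
                   iob_duration_h: float = 4.0,
                   iob_knots: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 0.9)),
                   cob_rate: float = 2.5, cob_delay_min: float = 15.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(IOB, COB) evaluated at every grid time (vectorized superposition)."""
    t_s = times.asi8 / 1e9
    iob = np.zeros(len(times))
    bol = events.boluses
    if len(bol):
        if (bol["value"] < 0).any():
            raise InvalidArgumentError("bolus doses must be nonnegative")
        ev_s = bol["timestamp"].astype("int64").to_numpy() / 1e9
        elapsed_h = (t_s[:, None] - ev_s[None, :]) / 3600.0
        iob = (iob_remaining_fraction(elapsed_h, iob_duration_h, iob_knots)
               * bol["value"].to_numpy()[None, :]).sum(axis=1)
    cob = np.zeros(len(times))
    meals = events.meals
    if len(meals):
        if (meals["value"] < 0).any():
            raise InvalidArgumentError("carbohydrate amounts must be nonnegative")
        ev_s = meals["timestamp"].astype("int64").to_numpy() / 1e9
        elapsed_min = (t_s[:, None] - ev_s[None, :]) / 60.0
        c = meals["value"].to_numpy()[None, :]
        absorbed = np.clip((elapsed_min - cob_delay_min) * cob_rate, 0.0, None)
        per = np.where(elapsed_min < 0, 0.0, np.clip(c - absorbed, 0.0, None))
        cob = per.sum(axis=1)
    return iob, cob


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Grid-aligned named feature columns with the original missingness mask
    (taken before interpolation) and, once fitted, min-max constants."""

    frame: pd.DataFrame                 # includes 'timestamp' column
    observed: pd.DataFrame              # bool per feature column, pre-interpolation
    norm_constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["timestamp"])

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "timestamp"]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.frame.copy(), self.observed.copy(),
                             dict(self.norm_constants))


def assemble_feature_matrix(cgm: CgmSeries, events: EventLog,
                            wristband_features: pd.DataFrame | None = None,
                            time_encoding: str = "linear", **onboard_kwargs
                            ) -> FeatureMatrix:
    """Join glucose, IOB/COB, time-of-day index and wristband features on the
    CGM grid. ``time_index`` is minutes-since-midnight scaled to [0, 1)
    (set ``time_encoding='sincos'`` for a circular encoding)."""
    iob, cob = onboard_series(events, cgm.times, **onboard_kwargs)
    frame = pd.DataFrame({"timestamp": cgm.times, "glucose": cgm.glucose,
                          "cob": cob, "iob": iob})
    minutes = (cgm.times.hour * 60 + cgm.times.minute).to_numpy()
    if time_encoding == "sincos":
        frame["time_sin"] = np.sin(2 * np.pi * minutes / 1440.0)
        frame["time_cos"] = np.cos(2 * np.pi * minutes / 1440.0)
    else:
        frame["time_index"] = minutes / 1440.0
    if wristband_features is not None:
        wf = wristband_features.set_index("timestamp")
        wf = wf.reindex(cgm.times)
        for col in wf.columns:
            frame[col] = wf[col].to_numpy()
    observed = frame.drop(columns="timestamp").notna()
    return FeatureMatrix(frame=frame, observed=observed)


def interpolate_gaps(matrix: FeatureMatrix, tail_mode: str = "carry_forward"
                     ) -> FeatureMatrix:
    """Fill interior gaps linearly and tail gaps causally.

    Interior gaps are linearly interpolated between flanking observations.
    Trailing gaps carry the last observation forward (``tail_mode='slope'``
    instead extrapolates the last local slope) — never using later samples.
    Leading gaps stay NaN and invalidate the windows that touch them.
    All-missing columns are left untouched and reported as unusable.
    """
    out = matrix.copy()
    for col in out.feature_columns:
        s = out.frame[col]
        if s.notna().sum() == 0:
            continue  # unusable; build_windows will drop windows touching it
        filled = s.interpolate(method="linear", limit_area="inside")
        if tail_mode == "slope":
            obs_idx = np.flatnonzero(s.notna().to_numpy())
            last = obs_idx[-1]
            if last < len(s) - 1 and len(obs_idx) >= 2:
                slope = s.iloc[obs_idx[-1]] - s.iloc[obs_idx[-2]]
                steps = np.arange(1, len(s) - last)
                filled.iloc[last + 1:] = s.iloc[last] + slope * steps
        else:
            filled = filled.ffill()
        out.frame[col] = filled
    return out


def unusable_columns(matrix: FeatureMatrix) -> list[str]:
    return [c for c in matrix.feature_columns if matrix.frame[c].notna().sum() == 0]


@dataclass
class MinMaxScaler:
    """Column-wise min-max map fitted on training rows only."""

    constants: dict[str, tuple[float, float]]

    def transform_col(self, col: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.constants[col]
        return (x - lo) / (hi - lo)

    def inverse_col(self, col: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.constants[col]
        return x * (hi - lo) + lo

    def scale_col(self, col: str) -> float:
        lo, hi = self.constants[col]
        return hi - lo


def minmax_fit_transform(matrix: FeatureMatrix, fit_rows: slice | np.ndarray
                         ) -> tuple[FeatureMatrix, MinMaxScaler]:
    """Scale each column by the min/max of the training rows; values outside
    the training range map outside [0, 1] (by design)."""
    out = matrix.copy()
    constants: dict[str, tuple[float, float]] = {}
    for col in out.feature_columns:
        train_vals = out.frame[col].to_numpy()[fit_rows]
        train_vals = train_vals[~np.isnan(train_vals)]
        if train_vals.size == 0:
            continue
        lo, hi = float(train_vals.min()), float(train_vals.max())
        if hi - lo == 0.0:
            raise InvalidArgumentError(f"column '{col}' is constant on the fit range")
        constants[col] = (lo, hi)
        out.frame[col] = (out.frame[col] - lo) / (hi - lo)
    out.norm_constants = constants
    return out, MinMaxScaler(constants)


@dataclass
class TargetScaler:
    """Min-max normalization m for the glucose-change target, with both the
    affine inverse and the pure scale (used to de-normalize an uncertainty)."""

    lo: float
    hi: float

    @classmethod
    def fit(cls, deltas: np.ndarray) -> "TargetScaler":
        d = deltas[~np.isnan(deltas)]
        if d.size == 0 or d.max() == d.min():
            raise InvalidArgumentError("cannot fit target scaler: degenerate deltas")
        return cls(float(d.min()), float(d.max()))

    def transform(self, delta: np.ndarray) -> np.ndarray:
        return (delta - self.lo) / (self.hi - self.lo)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * (self.hi - self.lo) + self.lo

    @property
    def scale(self) -> float:
        return self.hi - self.lo


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def candidate_combinations(columns: list[str],
                           ibi_group: tuple[str, ...] = IBI_GROUP,
                           eda_group: tuple[str, ...] = EDA_GROUP,
                           core: tuple[str, ...] = CORE_FEATURES) -> list[tuple[str, ...]]:
    """All feature sets keeping the core features plus exactly one member of
    each available collinearity group."""
    ibis = [c for c in ibi_group if c in columns] or [None]
    edas = [c for c in eda_group if c in columns] or [None]
    combos = []
    for i, e in itertools.product(ibis, edas):
        extra = tuple(c for c in (i, e) if c is not None)
        combos.append(tuple(c for c in core if c in columns) + extra)
    return combos


def select_features(validation_errors: dict[tuple[str, ...], float]
                    ) -> tuple[str, ...]:
    """Pick the combination minimizing summed validation RMSE over the four
    horizons; ties break to fewer features, then lexicographic order."""
    if not validation_errors:
        raise InvalidArgumentError("empty candidate set")
    return min(validation_errors,
               key=lambda k: (validation_errors[k], len(k), tuple(sorted(k))))


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Model-ready windows for one horizon: X[i] ends at index t_idx[i] and
    the (normalized) target is the glucose change to t_idx[i] + w."""

    X: np.ndarray          # (n, l, c) normalized features
    y_delta: np.ndarray    # (n,) raw glucose change G_{t+w} - G_t (mg/dL)
    t_idx: np.ndarray      # (n,) anchor grid indices
    g_anchor: np.ndarray   # (n,) G_t in mg/dL
    g_target: np.ndarray   # (n,) G_{t+w} in mg/dL
    horizon_steps: int
    columns: tuple[str, ...] = ()
    times: pd.DatetimeIndex | None = None

    def __len__(self) -> int:
        return len(self.y_delta)

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(self.X[idx], self.y_delta[idx], self.t_idx[idx],
                         self.g_anchor[idx], self.g_target[idx],
                         self.horizon_steps, self.columns,
                         self.times[idx] if self.times is not None else None)


def build_windows(matrix: FeatureMatrix, columns: tuple[str, ...] = DEFAULT_SELECTED,
                  l: int = 12, horizons: tuple[int, ...] = DEFAULT_HORIZONS,
                  glucose_mgdl: np.ndarray | None = None,
                  glucose_observed: np.ndarray | None = None
                  ) -> dict[int, WindowSet]:
    """Slide a length-``l`` window at every grid step; one WindowSet per
    horizon. A window is kept only when all l feature rows are finite, the
    anchor glucose G_t is an *observed* (not interpolated) reading, and so is
    the target G_{t+w}. ``glucose_mgdl`` supplies raw mg/dL glucose when the
    matrix itself is normalized.
    """
    if l < 1:
        raise InvalidArgumentError("window length l must be >= 1")
    cols = [c for c in columns if c in matrix.feature_columns]
    data = matrix.frame[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if glucose_mgdl is None:
        glucose_mgdl = matrix.frame["glucose"].to_numpy(dtype=float)
    if glucose_observed is None:
        glucose_observed = matrix.observed["glucose"].to_numpy()
    row_ok = np.isfinite(data).all(axis=1)

    out: dict[int, WindowSet] = {}
    for w in horizons:
        xs, ys, ts = [], [], []
        for t in range(l - 1, n - w):
            if not row_ok[t - l + 1: t + 1].all():
                continue
            if not (glucose_observed[t] and glucose_observed[t + w]):
                continue
            xs.append(data[t - l + 1: t + 1])
            ys.append(glucose_mgdl[t + w] - glucose_mgdl[t])
            ts.append(t)
        t_idx = np.asarray(ts, int)
        out[w] = WindowSet(
            X=np.asarray(xs, float).reshape(-1, l, len(cols)),
            y_delta=np.asarray(ys, float),
            t_idx=t_idx,
            g_anchor=glucose_mgdl[t_idx] if len(ts) else np.empty(0),
            g_target=glucose_mgdl[t_idx + w] if len(ts) else np.empty(0),
            horizon_steps=w,
            columns=tuple(cols),
            times=matrix.times[t_idx] if len(ts) else matrix.times[:0],
        )
    return out


def prepare_subject_windows(cgm: CgmSeries, events: EventLog,
                            wristband_features: pd.DataFrame | None,
                            columns: tuple[str, ...] = DEFAULT_SELECTED,
                            l: int = 12, horizons: tuple[int, ...] = DEFAULT_HORIZONS,
                            fit_fraction: float = 0.5,
                            tail_mode: str = "carry_forward"
                            ) -> tuple[dict[int, WindowSet], MinMaxScaler]:
    """Full per-subject pipeline: assemble -> interpolate -> normalize (on the
    chronological training fraction) -> window. Targets stay in raw mg/dL in
    the returned windows; the model layer owns the target normalization."""
    matrix = assemble_feature_matrix(cgm, events, wristband_features)
    matrix = interpolate_gaps(matrix, tail_mode=tail_mode)
    fit_rows = slice(0, int(len(matrix.frame) * fit_fraction))
    glucose_raw = matrix.frame["glucose"].to_numpy().copy()
    normed, scaler = minmax_fit_transform(matrix, fit_rows)
    windows = build_windows(normed, columns, l, horizons,
                            glucose_mgdl=glucose_raw,
                            glucose_observed=matrix.observed["glucose"].to_numpy())
    return windows, scaler


__all__ = [
    "FeatureMatrix", "WindowSet", "MinMaxScaler", "TargetScaler",
    "insulin_on_board", "carbohydrate_on_board", "iob_remaining_fraction",
    "onboard_series", "assemble_feature_matrix", "interpolate_gaps",
    "unusable_columns", "minmax_fit_transform", "candidate_combinations",
    "select_features", "build_windows", "prepare_subject_windows",
    "CORE_FEATURES", "IBI_GROUP", "EDA_GROUP", "DEFAULT_SELECTED",
    "DEFAULT_HORIZONS",
]
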