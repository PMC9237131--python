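"""Core data containers shared across the pipeline.

All time series live on one of two clocks: the canonical 5-minute CGM grid
(timezone-naive pandas timestamps) or a wristband channel's native sampling
clock (seconds since the channel start). Missing values are NaN; a separate
boolean mask is never stored because NaN-ness *is* the missingness mask for
gridded data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_STEP_MIN = 5
GRID_STEP = pd.Timedelta(minutes=GRID_STEP_MIN)

#: Commercial CGM sensors report within this range; the simulator clamps to it.
CGM_RANGE_MGDL = (40.0, 400.0)

#: Clinical glycemic thresholds (mg/dL).
HYPO_MGDL = 70.0
HYPER_MGDL = 180.0

#: Empatica-E4-style channel sampling rates (Hz).
WRISTBAND_RATES = {"bvp": 64.0, "eda": 4.0, "acc": 32.0, "temp": 4.0}


class InvalidArgumentError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass
class CgmSeries:
    """Glucose on a fixed 5-minute grid; NaN marks a missing reading."""

    times: pd.DatetimeIndex
    glucose: np.ndarray  # mg/dL, NaN where missing

    def __post_init__(self) -> None:
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.times) != len(self.glucose):
            raise InvalidArgumentError("times and glucose lengths differ")
        if len(self.times) > 1:
            deltas = np.diff(self.times.asi8)
            if not np.all(deltas == GRID_STEP.value):
                raise InvalidArgumentError("CGM timestamps must be on a uniform 5-min grid")

    def __len__(self) -> int:
        return len(self.glucose)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.glucose)

    def missing_fraction(self) -> float:
        return float(np.isnan(self.glucose).mean()) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "glucose_mgdl": self.glucose})

    def copy(self) -> "CgmSeries":
        return CgmSeries(self.times.copy(), self.glucose.copy())


@dataclass
class EventLog:
    """Timestamped daily entries: meals (g carbohydrate), boluses (U insulin),
    optional binary daily-event flags (exercise/alcohol/stress/illness)."""

    frame: pd.DataFrame  # columns: timestamp, type, value, units

    COLUMNS = ("timestamp", "type", "value", "units")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise InvalidArgumentError(f"EventLog missing columns: {sorted(missing)}")
        self.frame = self.frame.sort_values("timestamp", kind="stable").reset_index(drop=True)

    @classmethod
    def empty(cls) -> "EventLog":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                 zip(cls.COLUMNS, ("datetime64[ns]", "object", "float", "object"))}))

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.frame[self.frame["type"] == kind]

    @property
    def meals(self) -> pd.DataFrame:
        return self.of_type("meal")

    @property
    def boluses(self) -> pd.DataFrame:
        return self.of_type("bolus")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class Channel:
    """One wristband channel at its native rate. ``values`` is (n,) or (n, k)
    for multi-axis channels; NaN rows mark gaps."""

    start: pd.Timestamp
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def sample_times_s(self) -> np.ndarray:
        """Sample offsets in seconds from ``start``."""
        return np.arange(self.n) / self.fs

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(self.sample_times_s(), unit="s")

    def missing_fraction(self) -> float:
        if self.n == 0:
            return 0.0
        flat = self.values.reshape(self.n, -1)
        return float(np.isnan(flat).any(axis=1).mean())

    def copy(self) -> "Channel":
        return Channel(self.start, self.fs, self.values.copy())


@dataclass
class WristbandStreams:
    """Raw wristband channels (BVP, EDA, 3-axis ACC, skin TEMP)."""

    bvp: Channel
    eda: Channel
    acc: Channel
    temp: Channel

    def channels(self) -> dict[str, Channel]:
        return {"bvp": self.bvp, "eda": self.eda, "acc": self.acc, "temp": self.temp}

    def missing_fraction(self) -> float:
        """Sample-weighted missing fraction across channels."""
        total = sum(ch.n for ch in self.channels().values())
        if total == 0:
            return 0.0
        miss = sum(ch.missing_fraction() * ch.n for ch in self.channels().values())
        return float(miss / total)

    def copy(self) -> "WristbandStreams":
        return WristbandStreams(*(ch.copy() for ch in
                                  (self.bvp, self.eda, self.acc, self.temp)))


@dataclass
class SubjectParams:
    """Per-subject physiological parameters driving the simulator."""

    subject_id: str
    insulin_sensitivity: float = 50.0   # mg/dL drop per U
    carb_ratio: float = 10.0            # g carbohydrate per U bolus
    basal_glucose: float = 140.0        # mg/dL equilibrium
    glucose_noise_sd: float = 6.0       # mg/dL, AR(1) sensor/physiology noise
    mean_ibi: float = 0.85              # s
    ibi_sd: float = 0.05                # s
    scl_baseline: float = 2.0           # microsiemens
    scr_rate: float = 6.0               # events per hour
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insulin_sensitivity <= 0:
            raise InvalidArgumentError("insulin_sensitivity must be > 0")
        if not 70.0 <= self.basal_glucose <= 250.0:
            raise InvalidArgumentError("basal_glucose must lie in [70, 250] mg/dL")
        if not 0.4 <= self.mean_ibi <= 1.5:
            raise InvalidArgumentError("mean_ibi must lie in [0.4, 1.5] s")
        for name in ("carb_ratio", "glucose_noise_sd", "ibi_sd", "scl_baseline", "scr_rate"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """Everything the simulator knows that a real device would not report.

    Serves as the oracle for signal-recovery and event-detection tests.
    """

    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))      # s
    true_ibis: np.ndarray = field(default_factory=lambda: np.empty(0))       # s
    scr_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))      # s
    scr_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))  # µS
    tonic_trace: np.ndarray = field(default_factory=lambda: np.empty(0))     # µS per EDA sample
    phasic_trace: np.ndarray = field(default_factory=lambda: np.empty(0))    # µS per EDA sample
    event_windows: list = field(default_factory=list)  # (start, end, "hypo"|"hyper")

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, float)
        if bt.size and np.any(np.diff(bt) <= 0):
            raise InvalidArgumentError("beat_times must be strictly increasing")
        if np.any(np.asarray(self.scr_amplitudes, float) < 0):
            raise InvalidArgumentError("scr_amplitudes must be nonnegative")


@dataclass
class SubjectData:
    """One subject's simulated record."""

    params: SubjectParams
    cgm: CgmSeries
    events: EventLog
    wristband: WristbandStreams | None
    ground_truth: GroundTruth
    grid_physio: pd.DataFrame | None = None  # 5-min wristband-derived features


def regular_grid(start: pd.Timestamp, n: int) -> pd.DatetimeIndex:
    """A length-``n`` 5-minute grid starting at ``start``."""
    return pd.date_range(start, periods=n, freq=f"{GRID_STEP_MIN}min")


__all__ = [
    "CgmSeries", "EventLog", "Channel", "WristbandStreams", "SubjectParams",
    "GroundTruth", "SubjectData", "InvalidArgumentError", "regular_grid",
    "GRID_STEP_MIN", "GRID_STEP", "CGM_RANGE_MGDL", "HYPO_MGDL", "HYPER_MGDL",
    "WRISTBAND_RATES",
]
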