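"""Wristband signal processing: beats from BVP, tonic/phasic EDA, HRV, and
alignment of everything onto the 5-minute CGM grid.

Beat detection follows the slope-sum approach: the band-passed pulse waveform
is reduced to a windowed sum of its positive slopes, whose local maxima mark
systolic upstrokes; an adaptive threshold (a fraction of the running median of
recent accepted peaks) and a refractory period reject noise and double
detections. Every grid feature averages only the trailing 5-minute window, so
no feature at time t can see data after t.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt, welch

from .datatypes import InvalidArgumentError, WristbandStreams


@dataclass
class IbiSeries:
    """Inter-beat intervals with per-interval validity flags."""

    beat_times: np.ndarray   # s, strictly increasing
    ibis: np.ndarray         # s, len = len(beat_times) - 1
    quality_mask: np.ndarray  # bool per interval; False = artifact

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, float)
        self.ibis = np.asarray(self.ibis, float)
        self.quality_mask = np.asarray(self.quality_mask, bool)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise InvalidArgumentError("beat_times must be strictly increasing")

    @property
    def valid_ibis(self) -> np.ndarray:
        return self.ibis[self.quality_mask]


@dataclass
class EdaComponents:
    """Additive tonic (SCL) / phasic (SCR) split of an EDA trace."""

    scl: np.ndarray
    scr: np.ndarray


def bandpass_bvp(bvp: np.ndarray, fs: float, low_hz: float = 0.5,
                 high_hz: float = 8.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass; retains cardiac fundamentals and
    harmonics while removing baseline drift and high-frequency noise."""
    if not 0.0 < low_hz < high_hz < fs / 2.0:
        raise InvalidArgumentError("need 0 < low_hz < high_hz < fs/2")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(bvp, float))


def slope_sum(filtered: np.ndarray, window_samples: int) -> np.ndarray:
    """ssf[n] = sum over the trailing window of max(0, x[k] - x[k-1])."""
    if window_samples < 1:
        raise InvalidArgumentError("window_samples must be >= 1")
    x = np.asarray(filtered, float)
    pos = np.maximum(np.diff(x, prepend=x[:1]), 0.0)
    css = np.cumsum(pos)
    out = css.copy()
    out[window_samples:] -= css[:-window_samples]
    return out


def detect_beats(ssf: np.ndarray, fs: float, refractory_s: float = 0.3,
                 threshold_frac: float = 0.5, median_window: int = 8,
                 signal: np.ndarray | None = None,
                 ssf_window_samples: int | None = None) -> np.ndarray:
    """Beat times (s) from the slope-sum signal.

    Local maxima of ``ssf`` exceeding an adaptive threshold
    (``threshold_frac`` x running median of the last ``median_window``
    accepted peak amplitudes) are accepted; candidates inside the refractory
    period replace the previous beat only if larger. When the filtered
    waveform is supplied, each beat time is refined to the waveform maximum
    near the detection, removing the slope-sum window lag.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be > 0")
    ssf = np.asarray(ssf, float)
    if ssf.size < 3:
        return np.empty(0)
    is_peak = (ssf[1:-1] > ssf[:-2]) & (ssf[1:-1] >= ssf[2:]) & (ssf[1:-1] > 0)
    cand = np.flatnonzero(is_peak) + 1
    if cand.size == 0:
        return np.empty(0)

    refr = refractory_s * fs
    recent: list[float] = []
    accepted_idx: list[int] = []
    accepted_amp: list[float] = []
    # bootstrap threshold from the early candidate amplitudes
    boot = np.median(ssf[cand[: min(len(cand), 50)]])
    for i in cand:
        amp = ssf[i]
        thr = threshold_frac * (np.median(recent[-median_window:]) if recent else boot)
        if amp < thr:
            continue
        if accepted_idx and i - accepted_idx[-1] < refr:
            if amp > accepted_amp[-1]:
                accepted_idx[-1], accepted_amp[-1] = i, amp
                recent[-1] = amp
            continue
        accepted_idx.append(i)
        accepted_amp.append(amp)
        recent.append(amp)
    idx = np.asarray(accepted_idx, int)
    if idx.size == 0:
        return np.empty(0)

    if signal is not None:
        # slope-sum peaks trail the waveform peak by up to the ssf window;
        # snap each detection to the local waveform maximum
        sig = np.asarray(signal, float)
        lag = (ssf_window_samples or 0) // 2
        half = max(int(0.15 * fs), 1)
        refined = []
        for i in idx:
            c = max(i - lag, 0)
            lo, hi = max(c - half, 0), min(c + half + 1, sig.size)
            refined.append(lo + int(np.nanargmax(sig[lo:hi])))
        idx = np.asarray(refined, int)
        idx = idx[np.concatenate(([True], np.diff(idx) > 0))]
    return idx / fs


def compute_ibis(beat_times: np.ndarray, min_s: float = 0.3, max_s: float = 2.0) -> IbiSeries:
    """Successive differences of beat times; intervals outside [min_s, max_s]
    are flagged invalid (artifact rejection) but not deleted."""
    bt = np.asarray(beat_times, float)
    if bt.size and np.any(np.diff(bt) <= 0):
        raise InvalidArgumentError("beat_times must be strictly increasing")
    if bt.size < 2:
        return IbiSeries(bt, np.empty(0), np.empty(0, bool))
    ibis = np.diff(bt)
    return IbiSeries(bt, ibis, (ibis >= min_s) & (ibis <= max_s))


def detect_beats_from_bvp(bvp: np.ndarray, fs: float, low_hz: float = 0.5,
                          high_hz: float = 8.0, order: int = 3,
                          ssf_window_s: float = 0.128, **kwargs) -> np.ndarray:
    """Convenience chain: band-pass -> slope sum -> adaptive peak search.

    NaN gaps are zero-filled for filtering; beats inside gaps are discarded.
    """
    x = np.asarray(bvp, float)
    nan = np.isnan(x)
    filt = bandpass_bvp(np.where(nan, 0.0, x), fs, low_hz, high_hz, order)
    w = max(int(round(ssf_window_s * fs)), 1)
    ssf = slope_sum(filt, w)
    beats = detect_beats(ssf, fs, signal=filt, ssf_window_samples=w, **kwargs)
    if nan.any() and beats.size:
        beats = beats[~nan[np.minimum((beats * fs).astype(int), x.size - 1)]]
    return beats


def decompose_eda(eda: np.ndarray, fs: float, cutoff_hz: float = 0.01,
                  order: int = 2) -> EdaComponents:
    """High-pass split: phasic = zero-phase high-passed signal, tonic = rest.
    The split is exactly additive by construction."""
    if not 0.0 < cutoff_hz < fs / 2.0:
        raise InvalidArgumentError("need 0 < cutoff_hz < fs/2")
    x = np.asarray(eda, float)
    nan = np.isnan(x)
    filled = x
    if nan.any():
        idx = np.arange(x.size)
        filled = np.interp(idx, idx[~nan], x[~nan]) if (~nan).any() else np.zeros_like(x)
    sos = butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    scr = sosfiltfilt(sos, filled)
    scl = filled - scr
    scr = np.where(nan, np.nan, scr)
    scl = np.where(nan, np.nan, scl)
    return EdaComponents(scl=scl, scr=scr)


HRV_MISSING = float("nan")
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def hrv_features(ibi: IbiSeries, window_end: float, window_s: float = 300.0,
                 min_intervals: int = 10, resample_hz: float = 4.0) -> dict[str, float]:
    """Short-term HRV over the trailing window (window_end - window_s, window_end].

    Time domain: mean IBI, SDNN, RMSSD over valid intervals. Frequency domain:
    LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) power of the tachogram linearly
    resampled at ``resample_hz`` and estimated by Welch's periodogram.
    Windows with fewer than ``min_intervals`` valid intervals are missing.
    """
    keys = ("ibi_mean", "sdnn", "rmssd", "lf", "hf", "lf_hf")
    missing = {k: HRV_MISSING for k in keys}
    if ibi.ibis.size == 0:
        return missing
    t_int = ibi.beat_times[1:]  # interval stamped at its later beat
    in_win = (t_int > window_end - window_s) & (t_int <= window_end) & ibi.quality_mask
    vals = ibi.ibis[in_win]
    if vals.size < min_intervals:
        return missing
    out = {
        "ibi_mean": float(vals.mean()),
        "sdnn": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "rmssd": float(np.sqrt(np.mean(np.diff(vals) ** 2))) if vals.size > 1 else 0.0,
    }
    # tachogram -> uniform 4 Hz -> Welch
    tt = t_int[in_win]
    t_uni = np.arange(tt[0], tt[-1], 1.0 / resample_hz)
    if t_uni.size < 32:
        out.update({"lf": HRV_MISSING, "hf": HRV_MISSING, "lf_hf": HRV_MISSING})
        return out
    tach = np.interp(t_uni, tt, vals)
    f, pxx = welch(tach - tach.mean(), fs=resample_hz,
                   nperseg=min(256, t_uni.size))
    df = f[1] - f[0]
    lf = float(pxx[(f >= LF_BAND[0]) & (f < LF_BAND[1])].sum() * df)
    hf = float(pxx[(f >= HF_BAND[0]) & (f < HF_BAND[1])].sum() * df)
    out.update({"lf": lf, "hf": hf, "lf_hf": lf / hf if hf > 0 else HRV_MISSING})
    return out


def _trailing_mean(sample_s: np.ndarray, values: np.ndarray,
                   grid_s: np.ndarray, window_s: float = 300.0) -> np.ndarray:
    """Mean of samples in (t - window, t] for each grid time t; NaN if none."""
    order = np.argsort(sample_s, kind="stable")
    ts, vs = sample_s[order], values[order]
    keep = ~np.isnan(vs)
    ts, vs = ts[keep], vs[keep]
    out = np.full(grid_s.size, np.nan)
    if ts.size == 0:
        return out
    csum = np.concatenate(([0.0], np.cumsum(vs)))
    hi = np.searchsorted(ts, grid_s, side="right")
    lo = np.searchsorted(ts, grid_s - window_s, side="right")
    cnt = hi - lo
    nz = cnt > 0
    out[nz] = (csum[hi[nz]] - csum[lo[nz]]) / cnt[nz]
    return out


def align_to_grid(streams: WristbandStreams, grid: pd.DatetimeIndex,
                  window_s: float = 300.0, hrv_min_intervals: int = 10,
                  beat_times: np.ndarray | None = None) -> pd.DataFrame:
    """Per-grid-point wristband features, each averaging only the trailing
    5-minute window. Rows with no wristband coverage are NaN.

    Columns: ibi_mean, sdnn, rmssd, lf, hf, lf_hf, scl_mean, scr_mean,
    scr_count, activity, temp_mean.
    """
    if len(grid) > 1:
        step = np.diff(grid.asi8)
        if np.any(step <= 0):
            raise InvalidArgumentError("grid must be strictly increasing")
    t0 = streams.bvp.start
    grid_s = (grid.asi8 - t0.value) / 1e9

    if beat_times is None:
        beat_times = detect_beats_from_bvp(streams.bvp.values, streams.bvp.fs)
    ibi = compute_ibis(beat_times)
    hrv_rows = [hrv_features(ibi, ge, window_s, hrv_min_intervals) for ge in grid_s]
    out = pd.DataFrame(hrv_rows)
    out.insert(0, "timestamp", grid)

    eda = decompose_eda(streams.eda.values, streams.eda.fs)
    eda_t = streams.eda.sample_times_s()
    out["scl_mean"] = _trailing_mean(eda_t, eda.scl, grid_s, window_s)
    out["scr_mean"] = _trailing_mean(eda_t, eda.scr, grid_s, window_s)
    # SCR count: upward crossings of a small phasic threshold within the window
    thr = 0.05
    scr = np.nan_to_num(eda.scr, nan=-1.0)
    crossings = eda_t[1:][(scr[:-1] < thr) & (scr[1:] >= thr)]
    hi = np.searchsorted(crossings, grid_s, side="right")
    lo = np.searchsorted(crossings, grid_s - window_s, side="right")
    out["scr_count"] = (hi - lo).astype(float)
    out.loc[np.isnan(out["scr_mean"]), "scr_count"] = np.nan

    mag = np.sqrt(np.nansum(streams.acc.values ** 2, axis=1))
    mag[np.isnan(streams.acc.values).any(axis=1)] = np.nan
    out["activity"] = _trailing_mean(streams.acc.sample_times_s(), mag, grid_s, window_s)
    out["temp_mean"] = _trailing_mean(streams.temp.sample_times_s(),
                                      streams.temp.values, grid_s, window_s)
    return out


__all__ = [
    "IbiSeries", "EdaComponents", "bandpass_bvp", "slope_sum", "detect_beats",
    "detect_beats_from_bvp", "compute_ibis", "decompose_eda", "hrv_features",
    "align_to_grid",
]
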