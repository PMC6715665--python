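"""Cardiac-cycle landmarks from LV pressure and ECG.

Five landmarks anchor every beat: end-diastole (ED) at the ECG R peak,
the LV dP/dt maximum, mid-systole (MS) midway between the dP/dt maximum
and minimum, end-systole (ES) at the dP/dt minimum, and mid-diastole (MD)
midway between ES and the following dP/dt maximum.  Beat windows run
ED -> ED.  Per-beat parameter amplitudes are reported as the difference
between the Maximum and Minimum inside each window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import CoverageError, DetectionError, ValidationError

log = logging.getLogger(__name__)

LANDMARK_LABELS = ("ED", "MS", "ES", "MD")
DEFAULT_SMOOTH_WINDOW_MS = 7.0   # ~11 samples at 1613 Hz
DEFAULT_MIN_RR_S = 0.3


@dataclass
class BeatLandmarks:
    """Timestamps (s) of one annotated beat; window runs ED to the next ED."""

    ed: float
    dpdt_max: float
    ms: float
    es: float
    md: float
    window: tuple      # (start, end)

    def ordered(self) -> bool:
        start, end = self.window
        return (
            start <= self.ed <= self.dpdt_max < self.ms < self.es < self.md < end
        )

    def landmark(self, label: str) -> float:
        try:
            return {"ED": self.ed, "MS": self.ms, "ES": self.es, "MD": self.md}[label]
        except KeyError:
            raise ValidationError(f"unknown landmark label {label!r}") from None


@dataclass
class BeatExtrema:
    """Per-beat Maximum/Minimum of one parameter and their amplitude."""

    label: str
    beat: int
    vmax: float
    vmin: float
    change: float      # vmax - vmin, always >= 0
    t_max: float
    t_min: float


def compute_dpdt(
    lvp: np.ndarray, fs: float, smooth_window_ms: float = DEFAULT_SMOOTH_WINDOW_MS
) -> np.ndarray:
    """Smoothed first time derivative of LVP (mmHg/s), same length as input.

    A moving-window quadratic (Savitzky-Golay) smoother is applied before
    central differencing; both steps reproduce polynomials up to degree 2
    exactly, so constant and linear-ramp inputs give exact derivatives.
    Endpoints use one-sided differences.
    """
    lvp = np.asarray(lvp, dtype=float)
    if lvp.size < 3:
        raise ValidationError("compute_dpdt needs at least 3 samples")
    if not np.all(np.isfinite(lvp)):
        raise ValidationError("compute_dpdt requires finite LVP samples")
    if smooth_window_ms < 0:
        raise ValidationError("smooth_window_ms must be >= 0")
    return np.gradient(_smooth(lvp, fs, smooth_window_ms), 1.0 / fs)


def _smooth(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    """Moving-window quadratic smoother; exact on polynomials up to degree 2."""
    if window_ms <= 0:
        return x
    win = max(int(round(window_ms * 1e-3 * fs)), 5)
    if win % 2 == 0:
        win += 1
    if win > x.size:
        return x
    return savgol_filter(x, win, polyorder=2, mode="interp")


def detect_r_peaks(
    ecg: np.ndarray, fs: float, min_rr_s: float = DEFAULT_MIN_RR_S, t0: float = 0.0
) -> np.ndarray:
    """R-peak timestamps: prominent local maxima at least ``min_rr_s`` apart.

    The prominence threshold adapts to the record: half the excursion of
    the signal maximum above the median.  A flat record yields no peaks.
    """
    if min_rr_s <= 0:
        raise ValidationError("min_rr_s must be positive")
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0:
        return np.empty(0)
    excursion = float(ecg.max() - np.median(ecg))
    if excursion <= 0:
        return np.empty(0)
    idx, _ = find_peaks(
        ecg, prominence=0.5 * excursion, distance=max(1, int(round(min_rr_s * fs)))
    )
    return t0 + idx / fs


def annotate_beats(
    dpdt: np.ndarray, r_peaks: np.ndarray, fs: float, t0: float = 0.0
) -> list[BeatLandmarks]:
    """Annotate each RR interval with the five landmarks.

    Within each RR window the dP/dt maximum is located; ES is the dP/dt
    minimum between consecutive dP/dt maxima; MS and MD are arithmetic
    midpoints of their bracketing landmarks.  Because MD needs the next
    beat's dP/dt maximum, n R peaks yield at most n-2 complete beats.
    Beats violating the ordering invariant are dropped and reported.
    """
    dpdt = np.asarray(dpdt, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size < 2:
        raise DetectionError("annotate_beats needs at least 2 R peaks")
    if np.ptp(dpdt) == 0:
        raise DetectionError("dP/dt has no extrema")
    t = t0 + np.arange(dpdt.size) / fs

    dpmax_idx = []
    for k in range(r_peaks.size - 1):
        i0, i1 = np.searchsorted(t, [r_peaks[k], r_peaks[k + 1]])
        if i1 - i0 < 3:
            raise DetectionError(f"RR window {k} contains too few samples")
        dpmax_idx.append(i0 + int(np.argmax(dpdt[i0:i1])))

    beats, dropped = [], 0
    for k in range(len(dpmax_idx) - 1):
        j0, j1 = dpmax_idx[k], dpmax_idx[k + 1]
        es_idx = j0 + int(np.argmin(dpdt[j0:j1]))
        t_dpmax, t_es = t[j0], t[es_idx]
        beat = BeatLandmarks(
            ed=float(r_peaks[k]),
            dpdt_max=float(t_dpmax),
            ms=float(0.5 * (t_dpmax + t_es)),
            es=float(t_es),
            md=float(0.5 * (t_es + t[j1])),
            window=(float(r_peaks[k]), float(r_peaks[k + 1])),
        )
        if beat.ordered():
            beats.append(beat)
        else:
            dropped += 1
    if dropped:
        log.warning("annotate_beats: dropped %d beat(s) failing landmark ordering", dropped)
    return beats


def extract_extrema(
    t: np.ndarray,
    values: np.ndarray,
    beats: list[BeatLandmarks],
    n_beats: int = 10,
    label: str = "",
) -> list[BeatExtrema]:
    """Per-beat Maximum, Minimum and amplitude of a series over beat windows.

    The first ``n_beats`` complete beats are used; the series must cover
    every requested window.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(beats) < n_beats:
        raise CoverageError(f"only {len(beats)} complete beats available, {n_beats} requested")
    out = []
    slack = float(np.median(np.diff(t))) if t.size > 1 else 0.0  # one sample
    for b, beat in enumerate(beats[:n_beats]):
        start, end = beat.window
        if t[0] > start + slack or t[-1] < end - slack:
            raise CoverageError(f"series does not cover beat window [{start:.3f}, {end:.3f}] s")
        sel = (t >= start) & (t < end)
        seg, tseg = values[sel], t[sel]
        imax, imin = int(np.argmax(seg)), int(np.argmin(seg))
        out.append(
            BeatExtrema(
                label=label,
                beat=b,
                vmax=float(seg[imax]),
                vmin=float(seg[imin]),
                change=float(seg[imax] - seg[imin]),
                t_max=float(tseg[imax]),
                t_min=float(tseg[imin]),
            )
        )
    return out


def sample_at(
    t: np.ndarray, values: np.ndarray, beats: list[BeatLandmarks], landmark: str
) -> np.ndarray:
    """Linearly interpolated series value at one landmark of every beat."""
    if landmark not in LANDMARK_LABELS:
        raise ValidationError(f"landmark must be one of {LANDMARK_LABELS}")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    times = np.array([b.landmark(landmark) for b in beats])
    if times.size and (times.min() < t[0] or times.max() > t[-1]):
        raise CoverageError(f"landmark {landmark} falls outside the series support")
    return np.interp(times, t, values)


def heart_rate(beats: list[BeatLandmarks]) -> int:
    """Reported heart rate (min^-1): 60 / mean RR, rounded to the nearest integer."""
    if len(beats) < 2:
        raise DetectionError("heart_rate needs at least 2 beats")
    rr = np.array([b.window[1] - b.window[0] for b in beats])
    return int(round(60.0 / rr.mean()))


def mean_rr_s(beats: list[BeatLandmarks]) -> float:
    if len(beats) < 2:
        raise DetectionError("mean_rr_s needs at least 2 beats")
    return float(np.mean([b.window[1] - b.window[0] for b in beats]))


def transvalvular_gradient(
    t: np.ndarray,
    lvp: np.ndarray,
    aop: np.ndarray,
    beats: list[BeatLandmarks],
    smooth_window_ms: float = DEFAULT_SMOOTH_WINDOW_MS,
) -> np.ndarray:
    """Per-beat maximum of LVP - AoP over the ejection interval [dP/dt max, ES].

    The pressure difference is lightly smoothed (same quadratic window as
    the dP/dt computation) before the maximum is taken, so the peak
    statistic reflects the waveform rather than single-sample noise.
    """
    t = np.asarray(t, dtype=float)
    diff = np.asarray(lvp, dtype=float) - np.asarray(aop, dtype=float)
    if t.size > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
        diff = _smooth(diff, fs, smooth_window_ms)
    out = []
    for beat in beats:
        sel = (t >= beat.dpdt_max) & (t <= beat.es)
        if not sel.any():
            raise CoverageError("no samples inside the ejection interval")
        out.append(float(diff[sel].max()))
    return np.array(out)
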