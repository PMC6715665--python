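"""Strain-bridge calibration, force conversion and per-segment amplitudes.

Each transducer arm carries a Wheatstone half-bridge whose raw output is
linear in the applied radial load, so a per-arm least-squares line maps
raw units to Newtons.  Converted forces are zeroed at mid-diastole —
per-beat offsets interpolated between MD landmarks, which removes slow
drift without touching the Max-Min amplitudes — and summarized per beat
as the amplitude (Max - Min) and the landmark interval containing the
force peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .landmarks import BeatExtrema, BeatLandmarks, extract_extrema
from .signal_io import ARM_LABELS, AnalogueRecord

PEAK_PHASE_LABELS = ("ED-MS", "near-MS", "MS-ES", "ES-MD", "MD-ED")
NEAR_MS_FRACTION = 0.05   # of cycle length


@dataclass
class ForceCalibration:
    """Per-arm linear calibration: force (N) = slope * raw + intercept."""

    slope: dict          # arm -> N per raw unit, > 0
    intercept: dict      # arm -> N
    residual_rms: dict   # arm -> N


@dataclass
class ForceSeries:
    """Calibrated per-arm forces (N) zeroed at each beat's mid-diastole."""

    timestamps: np.ndarray
    force: dict          # arm -> array (N)
    zero_reference: str = "mid-diastole"


def fit_calibration(pairs: pd.DataFrame) -> ForceCalibration:
    """Least-squares line per arm from (load N, raw output) pairs.

    Requires at least two distinct loads per arm; a non-positive fitted
    slope signals a wiring/polarity fault and raises.
    """
    slope, intercept, rms = {}, {}, {}
    for arm in ARM_LABELS:
        sub = pairs[pairs["arm"] == arm]
        loads = sub["load_n"].to_numpy(dtype=float)
        raw = sub["raw"].to_numpy(dtype=float)
        if np.unique(loads).size < 2:
            raise CalibrationError(f"arm {arm}: need >= 2 distinct calibration loads")
        A = np.column_stack([raw, np.ones_like(raw)])
        (m, b), *_ = np.linalg.lstsq(A, loads, rcond=None)
        if m <= 0:
            raise CalibrationError(f"arm {arm}: non-positive calibration slope {m:g}")
        resid = loads - (m * raw + b)
        slope[arm], intercept[arm] = float(m), float(b)
        rms[arm] = float(np.sqrt(np.mean(resid**2)))
    return ForceCalibration(slope, intercept, rms)


def to_force(
    record: AnalogueRecord, cal: ForceCalibration, beats: list[BeatLandmarks]
) -> ForceSeries:
    """Convert raw strain channels to Newtons and zero them at mid-diastole.

    The per-beat offset is the calibrated force at each MD landmark;
    offsets are linearly interpolated between MDs (held constant beyond
    the first/last), so the value at every MD is exactly zero.
    """
    if set(cal.slope) != set(record.strain):
        raise ValidationError("calibration arms do not match strain channel labels")
    t = record.timestamps
    md_times = np.array([b.md for b in beats])
    out = {}
    for arm, raw in record.strain.items():
        f = cal.slope[arm] * raw + cal.intercept[arm]
        if md_times.size:
            offsets = np.interp(md_times, t, f)
            f = f - np.interp(t, md_times, offsets)
        out[arm] = f
    return ForceSeries(t, out)


def force_amplitudes(
    series: ForceSeries, beats: list[BeatLandmarks], n_beats: int = 10
) -> dict[str, list[BeatExtrema]]:
    """Per-arm per-beat Max-Min force amplitudes over the beat windows."""
    return {
        arm: extract_extrema(series.timestamps, f, beats, n_beats, label=arm)
        for arm, f in series.force.items()
    }


def peak_phase(
    series: ForceSeries, beats: list[BeatLandmarks], n_beats: int | None = None
) -> dict[str, list[str]]:
    """Label of the inter-landmark interval containing each beat's force peak.

    Peaks within ±5% of cycle length of MS are labelled ``near-MS``;
    otherwise the bracketing interval among ED-MS, MS-ES, ES-MD, MD-ED.
    """
    if n_beats is None:
        n_beats = len(beats)
    t = series.timestamps
    out: dict[str, list[str]] = {}
    for arm, f in series.force.items():
        labels = []
        for beat in beats[:n_beats]:
            start, end = beat.window
            sel = (t >= start) & (t < end)
            t_pk = t[sel][int(np.argmax(f[sel]))]
            rr = end - start
            if abs(t_pk - beat.ms) <= NEAR_MS_FRACTION * rr:
                labels.append("near-MS")
            elif t_pk < beat.ms:
                labels.append("ED-MS")
            elif t_pk < beat.es:
                labels.append("MS-ES")
            elif t_pk < beat.md:
                labels.append("ES-MD")
            else:
                labels.append("MD-ED")
        out[arm] = labels
    return out


def force_table(
    amplitudes: dict[str, list[BeatExtrema]], phases: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-beat force summary: ``beat,arm,fmax_n,fmin_n,change_n,peak_phase``."""
    rows = []
    for arm in ARM_LABELS:
        for ext, ph in zip(amplitudes[arm], phases[arm]):
            rows.append(
                {
                    "beat": ext.beat,
                    "arm": arm,
                    "fmax_n": ext.vmax,
                    "fmin_n": ext.vmin,
                    "change_n": ext.change,
                    "peak_phase": ph,
                }
            )
    return pd.DataFrame(rows)
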