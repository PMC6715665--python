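"""Plain-text dialects for the two acquisition streams, plus synchronization.

The sonomicrometry export is a TSV with a ``# fs_hz=`` comment header, a
``time_s`` column and 28 pair columns ``d_<i>_<j>`` (i<j, crystals 1..8,
mm).  The analogue record is a CSV with header
``time_s,lvp_mmhg,aop_mmhg,ecg_mv,strain_ln,strain_rn,strain_lr``.  Both
writers emit 6-decimal fixed precision, so a write/read round trip is exact
at that precision.

Synchronization follows the acquisition design: the LV dP/dt trace, present
in both systems when the sonomicrometry unit records its own LVP copy, is
cross-correlated to estimate the clock lag; without an LVP copy the lag is
the difference of the declared time origins.  Distance frames are then
resampled onto the analogue clock by linear interpolation (exact for
signals linear in time, no overshoot on 297 -> 1613 Hz upsampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .errors import AlignmentError, FormatError, ValidationError

log = logging.getLogger(__name__)

N_CRYSTALS = 8
PAIRS = [(i, j) for i in range(1, N_CRYSTALS + 1) for j in range(i + 1, N_CRYSTALS + 1)]
ARM_LABELS = ("LN", "RN", "LR")
ANALOGUE_COLUMNS = (
    "time_s", "lvp_mmhg", "aop_mmhg", "ecg_mv", "strain_ln", "strain_rn", "strain_lr"
)
MAX_DROPOUT_GAP_FRAMES = 5


# ---------------------------------------------------------------- containers

@dataclass
class DistanceSeries:
    """Time-stamped symmetric 8x8 inter-crystal distance matrices (mm)."""

    timestamps: np.ndarray            # (n,) s, strictly increasing
    distances: np.ndarray             # (n, 8, 8) mm, NaN diagonal / missing
    fs: float                         # Hz
    crystal_labels: tuple = tuple(range(1, N_CRYSTALS + 1))

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (self.timestamps.size, N_CRYSTALS, N_CRYSTALS):
            raise ValidationError("distances must have shape (n_frames, 8, 8)")
        _check_clock(self.timestamps, self.fs, "distance series")
        off = ~np.eye(N_CRYSTALS, dtype=bool)
        known = np.isfinite(self.distances) & off
        if not np.allclose(
            self.distances[known], np.swapaxes(self.distances, 1, 2)[known], atol=1e-9
        ):
            raise ValidationError("distance matrices must be symmetric")
        if np.any(self.distances[known] <= 0):
            raise ValidationError("distances must be positive or missing")

    @property
    def condensed(self) -> np.ndarray:
        """(n, 28) view of the upper-triangle pair distances in PAIRS order."""
        return np.stack([self.distances[:, i - 1, j - 1] for i, j in PAIRS], axis=1)

    @classmethod
    def from_condensed(cls, timestamps, cond, fs) -> "DistanceSeries":
        n = len(timestamps)
        D = np.full((n, N_CRYSTALS, N_CRYSTALS), np.nan)
        for k, (i, j) in enumerate(PAIRS):
            D[:, i - 1, j - 1] = cond[:, k]
            D[:, j - 1, i - 1] = cond[:, k]
        return cls(np.asarray(timestamps, float), D, fs)


@dataclass
class AnalogueRecord:
    """Time-aligned LVP/AoP (mmHg), ECG (mV) and three raw strain channels."""

    timestamps: np.ndarray
    lvp: np.ndarray
    aop: np.ndarray
    ecg: np.ndarray
    strain: dict                      # {"LN": array, "RN": array, "LR": array}
    fs: float

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = self.timestamps.size
        for name in ("lvp", "aop", "ecg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != n:
                raise ValidationError(f"channel {name} length mismatch")
        if set(self.strain) != set(ARM_LABELS):
            raise ValidationError(f"strain channels must be labelled {ARM_LABELS}")
        self.strain = {k: np.asarray(v, dtype=float) for k, v in self.strain.items()}
        for k, v in self.strain.items():
            if v.size != n:
                raise ValidationError(f"strain channel {k} length mismatch")
        _check_clock(self.timestamps, self.fs, "analogue record")


@dataclass
class AlignedDataset:
    """Distance frames resampled onto the analogue clock, with the lag used."""

    sono: DistanceSeries
    analogue: AnalogueRecord
    lag_s: float
    flagged: list = field(default_factory=list)   # (frame_index, reason)


def _check_clock(t: np.ndarray, fs: float, what: str) -> None:
    if t.size == 0:
        raise ValidationError(f"{what}: empty timestamps")
    if fs <= 0:
        raise ValidationError(f"{what}: fs must be positive")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{what}: timestamps must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / fs) > 0.01 / fs):
            raise ValidationError(f"{what}: sample spacing inconsistent with fs={fs} Hz")


# ------------------------------------------------------------------- writers

def _write_header(fh, fs: float, extra: dict | None = None) -> None:
    fh.write(f"# fs_hz={fs:g}\n")
    for k, v in (extra or {}).items():
        fh.write(f"# {k}={v}\n")


def write_distance_table(series: DistanceSeries, path) -> None:
    cond = series.condensed
    with open(path, "w") as fh:
        _write_header(fh, series.fs, {"crystals": N_CRYSTALS})
        cols = ["time_s"] + [f"d_{i}_{j}" for i, j in PAIRS]
        fh.write("\t".join(cols) + "\n")
        for t, row in zip(series.timestamps, cond):
            fh.write("\t".join(f"{x:.6f}" for x in np.concatenate([[t], row])) + "\n")


def write_analogue(record: AnalogueRecord, path) -> None:
    data = np.column_stack(
        [record.timestamps, record.lvp, record.aop, record.ecg]
        + [record.strain[a] for a in ARM_LABELS]
    )
    with open(path, "w") as fh:
        _write_header(fh, record.fs)
        fh.write(",".join(ANALOGUE_COLUMNS) + "\n")
        for row in data:
            fh.write(",".join(f"{x:.6f}" for x in row) + "\n")


def write_calibration(pairs: pd.DataFrame, path) -> None:
    """Calibration pairs CSV with columns ``arm,load_n,raw``."""
    pairs.to_csv(path, index=False, float_format="%.6f")


def write_flag_report(flagged: list, path) -> None:
    pd.DataFrame(flagged, columns=["frame_index", "reason"]).to_csv(path, index=False)


# ------------------------------------------------------------------- readers

def _read_declared_fs(path) -> float:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            line = line[1:].strip()
            if line.startswith("fs_hz="):
                return float(line.split("=", 1)[1])
    raise FormatError(f"{path}: missing '# fs_hz=' header")


def read_distance_table(path) -> DistanceSeries:
    fs = _read_declared_fs(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing time_s column")
    expected = [f"d_{i}_{j}" for i, j in PAIRS]
    for col in df.columns:
        if col == "time_s":
            continue
        if col not in expected:
            if col.startswith("d_"):
                raise FormatError(
                    f"{path}: pair column {col} is not an upper-triangle pair (i<j)"
                )
            raise FormatError(f"{path}: unexpected column {col}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pair column(s) {missing[:3]} ...")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    cond = df[expected].to_numpy(dtype=float)
    try:
        return DistanceSeries.from_condensed(t, cond, fs)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_analogue(path) -> AnalogueRecord:
    fs = _read_declared_fs(path)
    df = pd.read_csv(path, comment="#")
    for col in ANALOGUE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required channel column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    try:
        return AnalogueRecord(
            timestamps=t,
            lvp=df["lvp_mmhg"].to_numpy(float),
            aop=df["aop_mmhg"].to_numpy(float),
            ecg=df["ecg_mv"].to_numpy(float),
            strain={
                "LN": df["strain_ln"].to_numpy(float),
                "RN": df["strain_rn"].to_numpy(float),
                "LR": df["strain_lr"].to_numpy(float),
            },
            fs=fs,
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_calibration(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("arm", "load_n", "raw"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing calibration column {col}")
    return df


# ------------------------------------------------------- dropout interpolation

def fill_dropouts(
    series: DistanceSeries, max_gap_frames: int = MAX_DROPOUT_GAP_FRAMES
) -> tuple[DistanceSeries, list]:
    """Interpolate short missing-sample gaps; flag frames in longer gaps.

    Gaps of at most ``max_gap_frames`` consecutive missing frames in a pair
    channel are filled by linear interpolation in time; frames belonging to
    longer gaps (or gaps touching the record ends) stay missing and are
    reported so downstream geometry can exclude them.
    """
    cond = series.condensed.copy()
    t = series.timestamps
    bad_frames: set[int] = set()
    for k in range(cond.shape[1]):
        col = cond[:, k]
        isnan = ~np.isfinite(col)
        if not isnan.any():
            continue
        idx = np.flatnonzero(isnan)
        # split into consecutive runs
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            interior = run[0] > 0 and run[-1] < len(col) - 1
            if interior and len(run) <= max_gap_frames:
                good = np.flatnonzero(np.isfinite(col))
                col[run] = np.interp(t[run], t[good], col[good])
            else:
                bad_frames.update(run.tolist())
    filled = DistanceSeries.from_condensed(t, cond, series.fs)
    flagged = [(i, "dropout gap too long") for i in sorted(bad_frames)]
    return filled, flagged


# --------------------------------------------------------------- alignment

MIN_OVERLAP_S = 2.0


def align_streams(
    sono: DistanceSeries,
    analogue: AnalogueRecord,
    sono_lvp: np.ndarray | None = None,
    max_gap_frames: int = MAX_DROPOUT_GAP_FRAMES,
) -> AlignedDataset:
    """Synchronize the two streams and resample distances to the analogue clock.

    When the sonomicrometry system recorded its own LVP copy (``sono_lvp``,
    same length as the distance frames), the lag is found by maximizing the
    cross-correlation of the two LV dP/dt traces; otherwise the declared
    time origins are trusted and the lag is their difference.  ``lag_s`` is
    the amount by which the sono clock leads the analogue clock, i.e.
    ``t_analogue = t_sono - lag_s``.
    """
    if sono_lvp is not None:
        sono_lvp = np.asarray(sono_lvp, dtype=float)
        if sono_lvp.size != sono.timestamps.size:
            raise ValidationError("sono_lvp must match the distance-frame count")
        lag = _lag_by_dpdt(sono.timestamps, sono_lvp, analogue)
    else:
        lag = float(sono.timestamps[0] - analogue.timestamps[0])

    t_sono_on_analogue = sono.timestamps - lag
    start = max(t_sono_on_analogue[0], analogue.timestamps[0])
    end = min(t_sono_on_analogue[-1], analogue.timestamps[-1])
    if end - start < MIN_OVERLAP_S:
        raise AlignmentError(
            f"streams overlap only {max(end - start, 0):.3f} s after lag correction "
            f"(≥ {MIN_OVERLAP_S} s required)"
        )

    filled, flagged_sono = fill_dropouts(sono, max_gap_frames)
    sel = (analogue.timestamps >= start) & (analogue.timestamps <= end)
    ta = analogue.timestamps[sel]
    cond = filled.condensed
    out = np.empty((ta.size, cond.shape[1]))
    bad_resampled: set[int] = set()
    for k in range(cond.shape[1]):
        col = cond[:, k]
        good = np.isfinite(col)
        out[:, k] = np.interp(ta, t_sono_on_analogue[good], col[good])
        if not good.all():
            # analogue-clock frames bracketed by a missing sono frame stay flagged
            bad_t = t_sono_on_analogue[~good]
            gap = 1.0 / sono.fs
            for tb in bad_t:
                lo, hi = np.searchsorted(ta, [tb - gap, tb + gap])
                bad_resampled.update(range(lo, hi))

    resampled = DistanceSeries.from_condensed(ta, out, analogue.fs)
    trimmed = AnalogueRecord(
        timestamps=ta,
        lvp=analogue.lvp[sel],
        aop=analogue.aop[sel],
        ecg=analogue.ecg[sel],
        strain={k: v[sel] for k, v in analogue.strain.items()},
        fs=analogue.fs,
    )
    flagged = [(int(i), "interpolated across excluded sono frame") for i in sorted(bad_resampled)]
    log.info("align: lag_s=%.6f, %d resampled frames, %d flagged", lag, ta.size, len(flagged))
    return AlignedDataset(sono=resampled, analogue=trimmed, lag_s=lag, flagged=flagged)


def _lag_by_dpdt(t_sono: np.ndarray, sono_lvp: np.ndarray, analogue: AnalogueRecord) -> float:
    dt = 1.0 / analogue.fs
    # upsample the sono LVP copy to the analogue rate before differentiating
    t_up = np.arange(t_sono[0], t_sono[-1], dt)
    lvp_up = np.interp(t_up, t_sono, sono_lvp)
    d_sono = np.gradient(lvp_up, dt)
    d_ana = np.gradient(analogue.lvp, dt)
    a = d_ana - d_ana.mean()
    v = d_sono - d_sono.mean()
    c = correlate(a, v, mode="full")
    m = int(np.argmax(c)) - (v.size - 1)
    # sono feature at t_up[i] matches analogue sample i + m
    return float(t_up[0] - (analogue.timestamps[0] + m * dt))
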