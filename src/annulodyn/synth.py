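"""Synthetic beating-annulus generator with full ground truth.

Emulates the acute large-animal measurement setup the pipeline was built
for: six annular sonomicrometry crystals (three leaflet nadirs, three
commissures) plus apex and ascending-aorta reference crystals, sampled at
297 Hz; and an analogue record at 1613 Hz carrying LV pressure, aortic
pressure, an R-spike ECG and three strain-bridge channels driven by
per-arm radial forces.

Dynamics model (deliberately minimal):

* The six annular crystals move on a planar ellipse whose mean radius
  follows a raised-cosine activation in cardiac phase, peaking at
  mid-systole, and whose axis ratio interpolates from 1 at mid-diastole to
  ``ellipticity_max`` at mid-systole with the long axis along the
  NC-nadir <-> LR-commissure direction — oval in systole, round in
  diastole.  An optional small out-of-plane wobble exercises plane
  fitting.
* LVP is a raised-cosine systolic pulse with exactly one dP/dt maximum
  and one minimum per beat; the ECG R spike precedes the dP/dt maximum by
  a fixed electromechanical delay (40 ms).  AoP tracks LVP minus a
  gradient pulse while the valve is open and decays exponentially in
  diastole within the configured range.
* Per-arm force is a full-cycle raised cosine of the configured amplitude
  peaking at the configured landmark phase; strain channels are the
  inverse of the linear calibration applied to that force.

All channels carry additive Gaussian noise with configured SDs, drawn
from a single seeded generator, so identical protocol + seed reproduces
the dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .errors import ValidationError
from .signal_io import ARM_LABELS, AnalogueRecord, DistanceSeries

GEOMETRY_PARAMS = ("aaa_mm2", "aac_mm", "nc_mm", "rc_mm", "lc_mm", "d14_mm", "d25_mm", "d36_mm")

# fixed placement of the reference crystals (mm, annular frame)
APEX_POSITION = np.array([0.0, 0.0, -60.0])
AORTA_POSITION = np.array([4.0, 2.0, 40.0])

R_SPIKE_AMPLITUDE_MV = 1.2
R_SPIKE_SIGMA_S = 0.008
DIASTOLIC_TAU_S = 0.18
CALIBRATION_LOADS_N = (0.0, 1.25, 2.5, 3.75, 5.0)


@dataclass
class SimulationProtocol:
    """All generator parameters; defaults reproduce the study's conditions.

    ``force_peak_phase`` accepts either a cycle fraction in [0, 1) or one
    of the landmark labels ``ED, ED-MS, MS, MS-ES, ES, ES-MD, MD, MD-ED``
    (interval labels map to the interval midpoint).
    """

    heart_rate_bpm: float = 93.0
    n_beats: int = 13
    fs_sono: float = 297.0
    fs_analogue: float = 1613.0
    base_radius_mm: float = 12.0834
    radius_amplitude_mm: float = 0.7333
    ellipticity_max: float = 1.3
    segment_phase_lag_s: tuple = (0.0,) * 6
    lvp_range_mmHg: tuple = (8.0, 93.0)
    aop_range_mmHg: tuple = (55.0, 70.0)
    force_amplitude_N: dict = field(
        default_factory=lambda: {"LN": 1.20, "RN": 1.61, "LR": 2.87}
    )
    force_peak_phase: dict = field(
        default_factory=lambda: {"LN": "MS-ES", "RN": "MS-ES", "LR": "MS"}
    )
    distance_noise_sd_mm: float = 0.05
    analogue_noise_sd: dict = field(
        default_factory=lambda: {"lvp": 0.5, "aop": 0.5, "ecg": 0.02, "strain": 0.005}
    )
    rr_jitter_sd_s: float = 0.005
    wobble_amplitude_mm: float = 0.3
    systole_fraction: float = 0.45
    r_to_dpdtmax_s: float = 0.04
    calibration_slope_n_per_unit: dict = field(
        default_factory=lambda: {"LN": 2.0, "RN": 2.2, "LR": 2.5}
    )
    calibration_intercept_n: dict = field(
        default_factory=lambda: {"LN": 0.05, "RN": -0.03, "LR": 0.02}
    )
    calibration_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        positive = ("heart_rate_bpm", "fs_sono", "fs_analogue", "base_radius_mm")
        for key in positive:
            if getattr(self, key) <= 0:
                raise ValidationError(f"{key} must be positive")
        nonneg = (
            "radius_amplitude_mm", "distance_noise_sd_mm", "rr_jitter_sd_s",
            "wobble_amplitude_mm", "calibration_noise_sd", "r_to_dpdtmax_s",
        )
        for key in nonneg:
            if getattr(self, key) < 0:
                raise ValidationError(f"{key} must be >= 0")
        if self.n_beats < 1:
            raise ValidationError("n_beats must be >= 1")
        if self.ellipticity_max < 1:
            raise ValidationError("ellipticity_max must be >= 1")
        if not (0 < self.systole_fraction < 0.8):
            raise ValidationError("systole_fraction must lie in (0, 0.8)")
        if len(self.segment_phase_lag_s) != 6:
            raise ValidationError("segment_phase_lag_s needs one value per ring position")
        for name in ("lvp_range_mmHg", "aop_range_mmHg"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be (min, max) with min < max")
        if self.aop_range_mmHg[1] >= self.lvp_range_mmHg[1]:
            raise ValidationError("aop_range_mmHg max must lie below lvp_range_mmHg max")
        for mapping, what, lo in (
            (self.force_amplitude_N, "force_amplitude_N", 0.0),
            (self.calibration_slope_n_per_unit, "calibration_slope_n_per_unit", 1e-12),
        ):
            if set(mapping) != set(ARM_LABELS):
                raise ValidationError(f"{what} must have keys {ARM_LABELS}")
            for arm, v in mapping.items():
                if v < lo:
                    raise ValidationError(f"{what}[{arm}] must be >= {lo:g}")
        for key, v in self.analogue_noise_sd.items():
            if key not in ("lvp", "aop", "ecg", "strain"):
                raise ValidationError(f"unknown analogue_noise_sd channel {key!r}")
            if v < 0:
                raise ValidationError(f"analogue_noise_sd[{key}] must be >= 0")

    # --- landmark phases of the noise-free waveform model (cycle fractions) ---

    def landmark_phases(self, rr_s: float) -> dict:
        fsys = self.systole_fraction
        dpmax = self.r_to_dpdtmax_s / rr_s
        ms = dpmax + fsys / 4.0
        es = dpmax + fsys / 2.0
        md = 0.5 * (es + 1.0 + dpmax)
        return {"ED": 0.0, "dpdt_max": dpmax, "MS": ms, "ES": es, "MD": md}

    def peak_phase_fraction(self, arm: str, rr_s: float) -> float:
        setting = self.force_peak_phase[arm]
        if isinstance(setting, (int, float)):
            return float(setting) % 1.0
        lm = self.landmark_phases(rr_s)
        table = {
            "ED": lm["ED"],
            "ED-MS": 0.5 * (lm["ED"] + lm["MS"]),
            "MS": lm["MS"],
            "MS-ES": 0.5 * (lm["MS"] + lm["ES"]),
            "ES": lm["ES"],
            "ES-MD": 0.5 * (lm["ES"] + lm["MD"]),
            "MD": lm["MD"],
            "MD-ED": 0.5 * (lm["MD"] + 1.0),
        }
        try:
            return table[setting]
        except KeyError:
            raise ValidationError(
                f"unknown force_peak_phase label {setting!r}"
            ) from None


def build_protocol(config: dict | None = None) -> SimulationProtocol:
    """Build a validated protocol from a key-value mapping; unknown keys rejected.

    Dict-valued fields (noise SDs, per-arm maps) are merged into the
    defaults, so a partial override like ``{"analogue_noise_sd": {"ecg": 0}}``
    keeps the other channels at their default SDs.
    """
    config = dict(config or {})
    known = {f.name for f in dataclasses.fields(SimulationProtocol)}
    unknown = set(config) - known
    if unknown:
        raise ValidationError(f"unknown protocol key(s): {sorted(unknown)}")
    proto = SimulationProtocol()
    for key, value in config.items():
        current = getattr(proto, key)
        if isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            merged.update(value)
            setattr(proto, key, merged)
        elif isinstance(current, tuple):
            if np.isscalar(value):
                value = (float(value),) * len(current)
            setattr(proto, key, tuple(float(v) for v in value))
        elif isinstance(current, (int, np.integer)) and not isinstance(current, bool):
            setattr(proto, key, int(value))
        elif isinstance(current, float):
            setattr(proto, key, float(value))
        else:
            setattr(proto, key, value)
    proto.validate()
    return proto


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: landmarks, per-beat extrema, amplitudes."""

    beats: pd.DataFrame            # beat, ed_s, dpdtmax_s, ms_s, es_s, md_s, start_s, end_s
    geometry_extrema: pd.DataFrame  # beat, parameter, vmax, vmin, change
    force_amplitude_n: dict        # arm -> true Max-Min amplitude (N)
    hr_bpm: float
    transvalvular_gradient_mmHg: float
    seed: int
    frames: pd.DataFrame | None = None  # noise-free per-frame geometry (sono clock)

    def to_json(self, path) -> None:
        payload = {
            "beats": self.beats.to_dict(orient="list"),
            "geometry_extrema": self.geometry_extrema.to_dict(orient="list"),
            "force_amplitude_n": self.force_amplitude_n,
            "hr_bpm": self.hr_bpm,
            "transvalvular_gradient_mmHg": self.transvalvular_gradient_mmHg,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ------------------------------------------------------------------ internals

def _beat_grid(proto: SimulationProtocol, rng: np.random.Generator):
    """R-peak times and per-beat RR intervals (multiplicative jitter, ±3 SD clip)."""
    rr0 = 60.0 / proto.heart_rate_bpm
    eps = np.clip(rng.standard_normal(proto.n_beats), -3.0, 3.0)
    rr = rr0 + proto.rr_jitter_sd_s * eps
    if np.any(rr <= 0):
        raise ValidationError("rr_jitter_sd_s too large: non-positive cycle length")
    r_times = 0.15 + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    return r_times, rr


def _phase(t: np.ndarray, r_times: np.ndarray, rr: np.ndarray):
    """Cardiac phase (beat-local, R peak = 0), owning beat's RR and beat index."""
    k = np.clip(np.searchsorted(r_times, t, side="right") - 1, 0, len(rr) - 1)
    return (t - r_times[k]) / rr[k], rr[k], k


def _raised_cosine(phi: np.ndarray, peak: np.ndarray | float) -> np.ndarray:
    """Smooth periodic activation in [0, 1]: 1 at ``peak``, 0 half a cycle away."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (phi - peak)))


def _lvp_pulse_shape(phi, rr, proto: SimulationProtocol) -> np.ndarray:
    """Systolic pulse shape in [0, 1]; raised cosine over the systolic interval."""
    fsys = proto.systole_fraction
    phi_on = proto.r_to_dpdtmax_s / rr - fsys / 4.0
    # wrap so a pulse whose foot precedes the R peak stays continuous
    # across the beat boundary
    x = ((phi - phi_on) % 1.0) / fsys
    out = np.zeros_like(np.asarray(x, dtype=float))
    mask = (x >= 0.0) & (x <= 1.0)
    out[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[mask]))
    return out


def _annular_points(t: np.ndarray, proto: SimulationProtocol,
                    r_times: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """(n, 8, 3) noise-free crystal coordinates on the sono clock."""
    layout = geometry.DEFAULT_LAYOUT
    phi, rr_t, _ = _phase(t, r_times, rr)
    lm_ms = proto.r_to_dpdtmax_s / rr_t + proto.systole_fraction / 4.0
    ecc = 1.0 + (proto.ellipticity_max - 1.0) * _raised_cosine(phi, lm_ms)
    ax, bx = np.sqrt(ecc), 1.0 / np.sqrt(ecc)
    pts = np.empty((t.size, 8, 3))
    for pos, label in enumerate(layout.ring_order):
        theta = np.pi / 3.0 * pos
        phi_j = phi - proto.segment_phase_lag_s[pos] / rr_t
        r_j = proto.base_radius_mm + proto.radius_amplitude_mm * _raised_cosine(phi_j, lm_ms)
        pts[:, label - 1, 0] = r_j * ax * np.cos(theta)
        pts[:, label - 1, 1] = r_j * bx * np.sin(theta)
        pts[:, label - 1, 2] = proto.wobble_amplitude_mm * np.sin(
            2.0 * np.pi * (phi_j + pos / 6.0)
        )
    pts[:, 6, :] = APEX_POSITION
    pts[:, 7, :] = AORTA_POSITION
    return pts


def _analogue_waveforms(t: np.ndarray, proto: SimulationProtocol,
                        r_times: np.ndarray, rr: np.ndarray):
    """Noise-free LVP, AoP, ECG and per-arm force on the analogue clock."""
    phi, rr_t, beat_idx = _phase(t, r_times, rr)
    lvp_min, lvp_max = proto.lvp_range_mmHg
    aop_min, aop_max = proto.aop_range_mmHg
    g = _lvp_pulse_shape(phi, rr_t, proto)
    lvp = lvp_min + (lvp_max - lvp_min) * g

    # AoP: valve open -> LVP minus the gradient pulse; closed -> exponential decay
    grad = lvp_max - aop_max
    open_pressure = lvp_min + (lvp_max - lvp_min - grad) * g
    dt = float(np.median(np.diff(t)))
    decay = np.exp(-dt / DIASTOLIC_TAU_S)
    aop = np.empty_like(lvp)
    p = 0.5 * (aop_min + aop_max)
    for i in range(t.size):
        p = aop_min + (p - aop_min) * decay
        if open_pressure[i] > p:
            p = open_pressure[i]
        aop[i] = p

    ecg = np.zeros_like(t)
    for rt in r_times:
        ecg += R_SPIKE_AMPLITUDE_MV * np.exp(-0.5 * ((t - rt) / R_SPIKE_SIGMA_S) ** 2)

    force = {}
    for arm in ARM_LABELS:
        per_beat_peak = np.array([proto.peak_phase_fraction(arm, r) for r in rr])
        force[arm] = proto.force_amplitude_N[arm] * _raised_cosine(phi, per_beat_peak[beat_idx])
    return lvp, aop, ecg, force, grad


def _truth_landmarks(proto: SimulationProtocol, r_times: np.ndarray, rr: np.ndarray
                     ) -> pd.DataFrame:
    rows = []
    for k in range(proto.n_beats - 2):
        lm = proto.landmark_phases(rr[k])
        lm_next = proto.landmark_phases(rr[k + 1])
        es = r_times[k] + lm["ES"] * rr[k]
        dpmax_next = r_times[k + 1] + lm_next["dpdt_max"] * rr[k + 1]
        rows.append(
            {
                "beat": k,
                "ed_s": r_times[k],
                "dpdtmax_s": r_times[k] + lm["dpdt_max"] * rr[k],
                "ms_s": r_times[k] + lm["MS"] * rr[k],
                "es_s": es,
                "md_s": 0.5 * (es + dpmax_next),
                "start_s": r_times[k],
                "end_s": r_times[k + 1],
            }
        )
    return pd.DataFrame(rows)


def _truth_geometry_frames(t_sono, points) -> pd.DataFrame:
    layout = geometry.DEFAULT_LAYOUT
    rows = []
    for i in range(t_sono.size):
        pts = points[i]
        D = geometry.pairwise_distance_matrix(pts)
        chords = geometry.ring_chords(D, layout)
        sinus = geometry.sinus_lengths(D, layout)
        diam = geometry.cross_diameters(D, layout)
        rows.append(
            {
                "time_s": t_sono[i],
                "aaa_mm2": geometry.annulus_area(pts[:6], layout.ring_order),
                "aac_mm": chords.sum(),
                "nc_mm": sinus["NC"],
                "rc_mm": sinus["RC"],
                "lc_mm": sinus["LC"],
                "d14_mm": diam["NC-LR"],
                "d25_mm": diam["RC-LN"],
                "d36_mm": diam["LC-RN"],
            }
        )
    return pd.DataFrame(rows)


def _per_beat_extrema(frames: pd.DataFrame, beats: pd.DataFrame) -> pd.DataFrame:
    rows = []
    t = frames["time_s"].to_numpy()
    for _, b in beats.iterrows():
        sel = (t >= b["start_s"]) & (t < b["end_s"])
        for param in GEOMETRY_PARAMS:
            v = frames.loc[sel, param].to_numpy()
            rows.append(
                {
                    "beat": int(b["beat"]),
                    "parameter": param,
                    "vmax": float(v.max()),
                    "vmin": float(v.min()),
                    "change": float(v.max() - v.min()),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ main entry

def simulate_dataset(protocol: SimulationProtocol):
    """Generate one synthetic dataset.

    Returns ``(DistanceSeries, AnalogueRecord, calibration_pairs, SyntheticTruth)``
    where ``calibration_pairs`` is a DataFrame with columns ``arm, load_n, raw``.
    """
    protocol.validate()
    rng = np.random.default_rng(protocol.seed)
    r_times, rr = _beat_grid(protocol, rng)
    total = r_times[0] + rr.sum() + 0.15

    # --- sonomicrometry stream
    n_sono = int(np.floor(total * protocol.fs_sono))
    t_sono = np.arange(n_sono) / protocol.fs_sono
    points = _annular_points(t_sono, protocol, r_times, rr)
    diff = points[:, :, None, :] - points[:, None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    if protocol.distance_noise_sd_mm > 0:
        iu = np.triu_indices(8, 1)
        noise = rng.normal(0.0, protocol.distance_noise_sd_mm, (n_sono, len(iu[0])))
        for k, (i, j) in enumerate(zip(*iu)):
            dist[:, i, j] += noise[:, k]
            dist[:, j, i] = dist[:, i, j]
    for i in range(8):
        dist[:, i, i] = np.nan
    sono = DistanceSeries(t_sono, dist, protocol.fs_sono)

    # --- analogue stream
    n_ana = int(np.floor(total * protocol.fs_analogue))
    t_ana = np.arange(n_ana) / protocol.fs_analogue
    lvp, aop, ecg, force, grad = _analogue_waveforms(t_ana, protocol, r_times, rr)
    sd = protocol.analogue_noise_sd
    lvp_n = lvp + rng.normal(0.0, sd["lvp"], n_ana) if sd["lvp"] > 0 else lvp
    aop_n = aop + rng.normal(0.0, sd["aop"], n_ana) if sd["aop"] > 0 else aop
    ecg_n = ecg + rng.normal(0.0, sd["ecg"], n_ana) if sd["ecg"] > 0 else ecg
    strain = {}
    for arm in ARM_LABELS:
        f = force[arm]
        if sd["strain"] > 0:
            f = f + rng.normal(0.0, sd["strain"], n_ana)
        strain[arm] = (f - protocol.calibration_intercept_n[arm]) / (
            protocol.calibration_slope_n_per_unit[arm]
        )
    analogue = AnalogueRecord(t_ana, lvp_n, aop_n, ecg_n, strain, protocol.fs_analogue)

    # --- calibration pairs
    cal_rows = []
    for arm in ARM_LABELS:
        for load in CALIBRATION_LOADS_N:
            raw = (load - protocol.calibration_intercept_n[arm]) / (
                protocol.calibration_slope_n_per_unit[arm]
            )
            if protocol.calibration_noise_sd > 0:
                raw += rng.normal(0.0, protocol.calibration_noise_sd)
            cal_rows.append({"arm": arm, "load_n": load, "raw": raw})
    calibration = pd.DataFrame(cal_rows)

    # --- ground truth
    beats = _truth_landmarks(protocol, r_times, rr)
    frames = _truth_geometry_frames(t_sono, points)
    extrema = (
        _per_beat_extrema(frames, beats)
        if len(beats)
        else pd.DataFrame(columns=["beat", "parameter", "vmax", "vmin", "change"])
    )
    truth = SyntheticTruth(
        beats=beats,
        geometry_extrema=extrema,
        force_amplitude_n=dict(protocol.force_amplitude_N),
        hr_bpm=60.0 / rr.mean(),
        transvalvular_gradient_mmHg=float(grad),
        seed=protocol.seed,
        frames=frames,
    )
    return sono, analogue, calibration, truth
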