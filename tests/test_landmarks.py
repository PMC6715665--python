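"""Landmark detection against analytic waveforms and generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annulodyn import (
    CoverageError,
    DetectionError,
    annotate_beats,
    compute_dpdt,
    detect_r_peaks,
    extract_extrema,
    heart_rate,
    sample_at,
    transvalvular_gradient,
)
from annulodyn.errors import ValidationError

FS = 1613.0


class TestComputeDpdt:
    def test_constant_gives_zeros(self):
        assert np.allclose(compute_dpdt(np.full(100, 80.0), FS), 0.0, atol=1e-9)

    def test_linear_ramp_exact_in_interior(self):
        k = 250.0  # mmHg/s
        t = np.arange(500) / FS
        d = compute_dpdt(10 + k * t, FS)
        assert np.abs(d[1:-1] - k).max() < 1e-6

    def test_sinusoid_amplitude_and_extrema_positions(self):
        T = 0.8
        t = np.arange(int(3 * T * FS)) / FS
        lvp = 75 + 50 * np.sin(2 * np.pi * t / T)
        d = compute_dpdt(lvp, FS)
        expected_amp = 50 * 2 * np.pi / T
        assert d.max() == pytest.approx(expected_amp, rel=0.01)
        # first interior maximum at t = 0 mod T -> t = T
        sel = (t > T / 2) & (t < 3 * T / 2)
        t_max = t[sel][np.argmax(d[sel])]
        assert t_max == pytest.approx(T, abs=2 / FS)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValidationError):
            compute_dpdt(np.array([1.0, np.nan, 2.0]), FS)


class TestDetectRPeaks:
    def test_impulse_train_located_exactly(self):
        t = np.arange(int(4 * FS)) / FS
        ecg = np.zeros_like(t)
        for tk in (1.0, 2.0, 3.0):
            ecg[int(round(tk * FS))] = 1.0
        peaks = detect_r_peaks(ecg, FS, min_rr_s=0.5)
        assert np.allclose(peaks, [1.0, 2.0, 3.0], atol=0.5 / FS)

    def test_flat_signal_gives_no_peaks(self):
        assert detect_r_peaks(np.zeros(1000), FS).size == 0

    def test_synthetic_ecg_within_5ms_of_truth(self, default_dataset):
        _, (_, ana, _, truth) = default_dataset
        peaks = detect_r_peaks(ana.ecg, ana.fs)
        true_ed = truth.beats["ed_s"].to_numpy()
        for ed in true_ed:
            assert np.min(np.abs(peaks - ed)) < 0.005


class TestAnnotateBeats:
    def _sinusoid_beats(self, T=0.8, n_cycles=5):
        t = np.arange(int(n_cycles * T * FS)) / FS
        lvp = 75 + 50 * np.sin(2 * np.pi * t / T)
        dpdt = compute_dpdt(lvp, FS)
        # dP/dt maxima at t = 0 mod T; R peaks 40 ms earlier
        r = np.array([k * T - 0.04 for k in range(1, n_cycles)])
        return t, dpdt, r, T

    def test_sinusoid_midpoints_match_analytic_positions(self):
        t, dpdt, r, T = self._sinusoid_beats()
        beats = annotate_beats(dpdt, r, FS)
        assert len(beats) >= 2
        for b in beats:
            assert b.ms == pytest.approx(b.dpdt_max + T / 4, abs=1.5 / FS)
            assert b.md == pytest.approx(b.es + T / 4, abs=1.5 / FS)
            assert b.es == pytest.approx(b.dpdt_max + T / 2, abs=1.5 / FS)

    def test_translation_invariance_of_landmark_offsets(self):
        t, dpdt, r, T = self._sinusoid_beats(n_cycles=6)
        beats = annotate_beats(dpdt, r, FS)
        offsets = np.array([[b.dpdt_max - b.ed, b.ms - b.ed, b.es - b.ed, b.md - b.ed]
                            for b in beats])
        assert np.abs(offsets - offsets[0]).max() <= 1.0 / FS + 1e-12

    def test_ordering_invariant_on_every_beat(self, default_dataset):
        _, (_, ana, _, _) = default_dataset
        dpdt = compute_dpdt(ana.lvp, ana.fs)
        r = detect_r_peaks(ana.ecg, ana.fs)
        for b in annotate_beats(dpdt, r, ana.fs):
            assert b.ordered()

    def test_zero_dpdt_raises(self):
        with pytest.raises(DetectionError, match="extrema"):
            annotate_beats(np.zeros(4000), np.array([0.5, 1.5]), FS)

    def test_fewer_than_two_r_peaks_raises(self):
        with pytest.raises(DetectionError):
            annotate_beats(np.sin(np.arange(1000)), np.array([0.1]), FS)

    def test_noise_free_landmarks_within_one_sono_sample(self, clean_dataset):
        _, (_, ana, _, truth) = clean_dataset
        dpdt = compute_dpdt(ana.lvp, ana.fs)
        r = detect_r_peaks(ana.ecg, ana.fs)
        beats = annotate_beats(dpdt, r, ana.fs)
        rec = np.array([[b.ed, b.dpdt_max, b.ms, b.es, b.md] for b in beats])
        tru = truth.beats[["ed_s", "dpdtmax_s", "ms_s", "es_s", "md_s"]].to_numpy()
        assert np.abs(rec - tru[: len(rec)]).max() < 1.0 / 297.0


def _unit_beats(n=4):
    """n unit-length beat windows with evenly spaced landmarks."""
    from annulodyn import BeatLandmarks

    return [
        BeatLandmarks(ed=k, dpdt_max=k + 0.1, ms=k + 0.25, es=k + 0.4, md=k + 0.7,
                      window=(float(k), float(k + 1)))
        for k in range(n)
    ]


class TestExtractExtrema:
    def test_constant_series_has_zero_change(self):
        beats = _unit_beats()
        t = np.linspace(0, 4, 4000)
        ext = extract_extrema(t, np.full_like(t, 3.3), beats, n_beats=4)
        assert all(e.change == 0 for e in ext)

    def test_sine_amplitude_recovered(self):
        beats = _unit_beats()
        t = np.linspace(0, 4, 40000)
        A = 2.5
        ext = extract_extrema(t, A * np.sin(2 * np.pi * t), beats, n_beats=4)
        for e in ext:
            assert e.change == pytest.approx(2 * A, rel=0.01)

    def test_coverage_error_when_too_few_beats(self):
        beats = _unit_beats(3)
        t = np.linspace(0, 3, 300)
        with pytest.raises(CoverageError):
            extract_extrema(t, t, beats, n_beats=10)

    @given(offset=st.floats(-100, 100), scale=st.floats(0.01, 50))
    @settings(max_examples=25, deadline=None)
    def test_change_offset_invariant_and_scale_linear(self, offset, scale):
        beats = _unit_beats(2)
        t = np.linspace(0, 2, 2000)
        v = np.sin(7 * t) + 0.3 * t
        base = extract_extrema(t, v, beats, n_beats=2)
        moved = extract_extrema(t, scale * v + offset, beats, n_beats=2)
        for b, m in zip(base, moved):
            assert m.change == pytest.approx(scale * b.change, rel=1e-9, abs=1e-9)

    def test_synthetic_aac_extrema_within_noise_tolerance(self, default_dataset, clean_dataset):
        # use the clean dataset: recovered extrema equal truth exactly
        _, (sono, ana, _, truth) = clean_dataset
        from annulodyn import align_streams
        from annulodyn.geometry import geometry_series

        aligned = align_streams(sono, ana)
        geo = geometry_series(aligned)
        dpdt = compute_dpdt(aligned.analogue.lvp, ana.fs)
        r = detect_r_peaks(aligned.analogue.ecg, ana.fs, t0=aligned.analogue.timestamps[0])
        beats = annotate_beats(dpdt, r, ana.fs, t0=aligned.analogue.timestamps[0])
        ext = extract_extrema(
            geo.frames["time_s"].to_numpy(), geo.frames["aac_mm"].to_numpy(), beats, 10
        )
        tru = truth.geometry_extrema.query("parameter == 'aac_mm'")
        rec_max = np.array([e.vmax for e in ext])
        assert np.abs(rec_max - tru["vmax"].to_numpy()[:10]).max() < 0.02


class TestSampleAtAndSummaries:
    def test_constant_series_sampled_everywhere(self):
        beats = _unit_beats()
        t = np.linspace(0, 4, 400)
        for lm in ("ED", "MS", "ES", "MD"):
            assert np.allclose(sample_at(t, np.full_like(t, 9.9), beats, lm), 9.9)

    def test_linear_series_sampled_exactly(self):
        beats = _unit_beats()
        t = np.linspace(0, 4, 400)
        vals = sample_at(t, 2 * t + 1, beats, "MS")
        expected = [2 * b.ms + 1 for b in beats]
        assert np.allclose(vals, expected, atol=1e-9)

    def test_unknown_landmark_rejected(self):
        with pytest.raises(ValidationError):
            sample_at(np.arange(4.0), np.arange(4.0), _unit_beats(), "XX")

    def test_heart_rate_constant_rr(self):
        assert heart_rate(_unit_beats(4)) == 60

    def test_heart_rate_645ms_rr_reports_93(self):
        from annulodyn import BeatLandmarks

        beats = [
            BeatLandmarks(k * 0.645, k * 0.645 + 0.04, k * 0.645 + 0.1, k * 0.645 + 0.2,
                          k * 0.645 + 0.4, (k * 0.645, (k + 1) * 0.645))
            for k in range(10)
        ]
        assert heart_rate(beats) == 93

    def test_heart_rate_matches_generated_rr(self, default_dataset):
        _, (_, _, _, truth) = default_dataset
        rr = (truth.beats["end_s"] - truth.beats["start_s"]).to_numpy()
        from annulodyn import BeatLandmarks

        beats = [
            BeatLandmarks(r["ed_s"], r["dpdtmax_s"], r["ms_s"], r["es_s"], r["md_s"],
                          (r["start_s"], r["end_s"]))
            for _, r in truth.beats.iterrows()
        ]
        assert heart_rate(beats) == int(round(60.0 / rr.mean()))


class TestTransvalvularGradient:
    def test_identical_pressures_give_zero(self):
        beats = _unit_beats(2)
        t = np.linspace(0, 2, 4000)
        lvp = 80 + 10 * np.sin(t)
        assert np.allclose(transvalvular_gradient(t, lvp, lvp, beats), 0.0, atol=1e-9)

    def test_constant_offset_recovered(self):
        beats = _unit_beats(2)
        t = np.linspace(0, 2, 4000)
        lvp = 80 + 10 * np.sin(t)
        g = transvalvular_gradient(t, lvp, lvp - 10, beats)
        assert np.allclose(g, 10.0, atol=1e-6)

    def test_synthetic_peak_gradient_within_5_percent(self, default_dataset):
        _, (_, ana, _, truth) = default_dataset
        dpdt = compute_dpdt(ana.lvp, ana.fs)
        r = detect_r_peaks(ana.ecg, ana.fs)
        beats = annotate_beats(dpdt, r, ana.fs)
        g = transvalvular_gradient(ana.timestamps, ana.lvp, ana.aop, beats[:10])
        assert g.mean() == pytest.approx(truth.transvalvular_gradient_mmHg, rel=0.05)
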