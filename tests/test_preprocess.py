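"""Preprocessing chain: filtering, onset detection, outlier gate, templating."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import freqz

from ppgage.errors import (ConfigurationError, InputError,
                           NormalizationError, SegmentationError,
                           UnusableRecordingError)
from ppgage.preprocess import (PULSE_LENGTH, PulseSegment, _resample_cubic,
                               apply_fir, design_bandpass, detect_onsets,
                               filter_segments, ppi_outlier_bounds,
                               preprocess_recording, representative_pulse,
                               segment, smooth)
from ppgage.synth import CohortSpec, synth_pulse, synth_recording


class TestBandpassDesign:
    @pytest.mark.parametrize("fs", [125, 250])
    def test_taps_equal_sampling_rate(self, fs):
        spec = design_bandpass(fs)
        assert spec.n_taps == fs

    def test_linear_phase_symmetry(self):
        taps = design_bandpass(125).taps
        assert np.allclose(taps, taps[::-1])

    def test_band_shape(self):
        spec = design_bandpass(125)
        w, h = freqz(spec.taps, worN=8192, fs=125)
        mag = {f: abs(h[np.argmin(abs(w - f))]) for f in (0.05, 2.0, 30.0)}
        assert mag[2.0] > mag[0.05]
        assert mag[2.0] > mag[30.0]

    def test_unsupported_rate(self):
        with pytest.raises(ConfigurationError):
            design_bandpass(100)
        spec = design_bandpass(100, allow_any_rate=True)
        assert spec.n_taps == 100


class TestApplyFir:
    def test_respiration_attenuated_vs_pulse_band(self):
        fs, spec = 125, design_bandpass(125)
        t = np.arange(40 * fs) / fs
        gain = {}
        for f in (0.25, 2.0):
            out = apply_fir(np.sin(2 * np.pi * f * t), spec)
            mid = out[10 * fs:30 * fs]
            gain[f] = mid.std() * np.sqrt(2)
        assert gain[0.25] < gain[2.0]

    def test_zero_in_zero_out(self):
        spec = design_bandpass(125)
        out = apply_fir(np.zeros(1000), spec)
        assert np.allclose(out, 0)
        assert len(out) == 1000

    def test_group_delay_compensated(self, clean_recording):
        spec = design_bandpass(125)
        raw = clean_recording.signal
        filt = apply_fir(raw, spec)
        # compare argmax of an interior pulse before/after filtering
        a, b = clean_recording.log.onsets[5], clean_recording.log.onsets[6]
        assert abs(np.argmax(filt[a:b]) - np.argmax(raw[a:b])) <= 2

    def test_too_short_signal(self):
        with pytest.raises(InputError):
            apply_fir(np.zeros(50), design_bandpass(125))


class TestSmooth:
    def test_constant_preserved(self):
        assert np.allclose(smooth(np.full(100, 3.7), 125), 3.7)

    def test_window_rule_125hz(self):
        # 0.05 * 125 = 6.25 -> round 6 -> forced odd 7
        impulse = np.zeros(101)
        impulse[50] = 1.0
        out = smooth(impulse, 125)
        assert np.isclose(out[50], 1 / 7)
        assert np.count_nonzero(np.isclose(out, 1 / 7)) == 7

    def test_length_preserved(self):
        assert len(smooth(np.random.default_rng(0).random(333), 250)) == 333


class TestDetectOnsets:
    def test_beat_count_and_positions(self, zero_jitter_map):
        spec = CohortSpec(duration=19.0, ppi_jitter_sd=0, noise_sd=0,
                          respiration_amp=0, artifact_rate=0, ectopic_rate=0)
        rec = synth_recording(50, spec, seed=1, aging_map=zero_jitter_map)
        assert rec.log.n_beats >= 20
        fspec = design_bandpass(125)
        x = smooth(apply_fir(rec.signal, fspec), 125)
        onsets = detect_onsets(x, 125)
        assert abs(len(onsets) - rec.log.n_beats) <= 1
        errs = [min(abs(o - rec.log.onsets)) for o in onsets]
        assert max(errs) <= 2

    def test_flat_signal_empty(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert len(detect_onsets(np.zeros(2000), 125)) == 0

    def test_onsets_stable_outside_artifact(self, zero_jitter_map):
        spec = CohortSpec(duration=30.0, ppi_jitter_sd=0, noise_sd=0,
                          respiration_amp=0, artifact_rate=0, ectopic_rate=0)
        rec = synth_recording(50, spec, seed=4, aging_map=zero_jitter_map)
        fspec = design_bandpass(125)
        clean = smooth(apply_fir(rec.signal, fspec), 125)
        corrupted_sig = rec.signal.copy()
        burst = slice(10 * 125, 11 * 125)
        corrupted_sig[burst] += np.random.default_rng(0).normal(0, 3, 125)
        corrupted = smooth(apply_fir(corrupted_sig, fspec), 125)
        on_clean = detect_onsets(clean, 125)
        on_corr = detect_onsets(corrupted, 125)
        # onsets well away from the burst are unchanged
        far_clean = on_clean[(on_clean < 8 * 125) | (on_clean > 14 * 125)]
        far_corr = on_corr[(on_corr < 8 * 125) | (on_corr > 14 * 125)]
        assert np.array_equal(far_clean, far_corr)


class TestSegment:
    def test_arithmetic_example(self):
        sig = np.arange(300.0)
        segs, ppis = segment(sig, np.array([0, 100, 200]), 125)
        assert len(segs) == 2
        assert np.allclose(ppis, [0.8, 0.8])
        assert len(segs[0].samples) == 100

    def test_concatenation_recovers_signal(self):
        rng = np.random.default_rng(1)
        sig = rng.random(1000)
        onsets = np.array([10, 300, 455, 700, 990])
        segs, _ = segment(sig, onsets, 125)
        cat = np.concatenate([s.samples for s in segs])
        assert np.array_equal(cat, sig[10:990])

    def test_count_rule(self):
        sig = np.zeros(2300)
        onsets = np.arange(21) * 100
        segs, _ = segment(sig, onsets, 125)
        assert len(segs) == 20

    def test_too_few_onsets(self):
        with pytest.raises(SegmentationError):
            segment(np.zeros(100), np.array([5]), 125)


def _brute_force_gate(ppis, mode="qd"):
    """Independent oracle: literal evaluation of the bound formula."""
    q1 = np.quantile(ppis, 0.25)
    q3 = np.quantile(ppis, 0.75)
    spread = (q3 - q1) / 2 if mode == "qd" else q3 - q1
    lo, hi = q1 - 1.5 * spread, q3 + 1.5 * spread
    return [i for i, p in enumerate(ppis) if lo <= p <= hi]


class TestOutlierGate:
    def test_zero_spread(self):
        series = ppi_outlier_bounds(np.full(6, 0.8))
        assert series.bounds == (0.8, 0.8)
        segs = [PulseSegment(np.zeros(3), 0, 0.8)] * 6
        assert len(filter_segments(segs, series)) == 6

    def test_ectopic_interval_excluded(self):
        ppis = np.array([0.76, 0.78, 0.80, 0.82, 0.84, 2.0])
        series = ppi_outlier_bounds(ppis)
        # hand-evaluated linear-interpolation quantiles: Q1 at order
        # position 1.25 -> 0.785, Q3 at position 3.75 -> 0.835
        assert np.isclose(series.q1, 0.785)
        assert np.isclose(series.q3, 0.835)
        qd = (0.835 - 0.785) / 2
        assert np.isclose(series.lower_bound, 0.785 - 1.5 * qd)
        assert np.isclose(series.upper_bound, 0.835 + 1.5 * qd)
        segs = [PulseSegment(np.zeros(3), 0, p) for p in ppis]
        kept = filter_segments(segs, series)
        assert [s.ppi for s in kept] == [0.76, 0.78, 0.80, 0.82, 0.84]

    @given(st.lists(st.floats(0.3, 2.5), min_size=4, max_size=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_iqr_mode_never_narrows(self, ppis):
        qd = ppi_outlier_bounds(np.array(ppis), "qd")
        iqr = ppi_outlier_bounds(np.array(ppis), "iqr")
        assert iqr.lower_bound <= qd.lower_bound
        assert iqr.upper_bound >= qd.upper_bound

    @given(st.lists(st.floats(0.3, 2.5), min_size=4, max_size=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_gate_matches_brute_force(self, ppis):
        ppis = np.array(ppis)
        series = ppi_outlier_bounds(ppis)
        segs = [PulseSegment(np.zeros(3), 0, p) for p in ppis]
        try:
            kept = filter_segments(segs, series)
            kept_idx = [i for i, s in enumerate(segs)
                        if any(k is s for k in kept)]
        except UnusableRecordingError:
            kept_idx = []
        assert kept_idx == _brute_force_gate(ppis)

    def test_few_intervals_retains_all(self):
        with pytest.warns(UserWarning):
            series = ppi_outlier_bounds(np.array([0.8, 0.9]))
        assert series.bounds == (-np.inf, np.inf)

    def test_subset_property(self):
        rng = np.random.default_rng(0)
        ppis = rng.uniform(0.5, 1.5, 30)
        segs = [PulseSegment(np.zeros(3), 0, p) for p in ppis]
        kept = filter_segments(segs, ppi_outlier_bounds(ppis))
        assert len(kept) <= len(segs)
        assert all(any(k is s for s in segs) for k in kept)


class TestRepresentativePulse:
    def _make_segments(self, n, ppi=0.9, fs=125, corrupt=()):
        from ppgage.synth import PulseModelParams

        base = synth_pulse(PulseModelParams(), ppi, fs)
        segs = []
        for i in range(n):
            samples = base.copy()
            if i in corrupt:
                samples[30:35] += 5.0  # spike artifact
            segs.append(PulseSegment(samples, i * len(base), ppi))
        return segs

    def test_identical_segments(self):
        segs = self._make_segments(5)
        rep = representative_pulse(segs, 125)
        single = representative_pulse(segs[:1], 125)
        assert np.allclose(rep.samples, single.samples)
        assert rep.n_segments_used == 5

    def test_median_robust_to_corrupted_segment(self):
        clean = representative_pulse(self._make_segments(9), 125)
        mixed = representative_pulse(self._make_segments(10, corrupt={9}), 125)
        assert np.max(np.abs(clean.samples - mixed.samples)) < 0.05

    def test_output_contract(self):
        rep = representative_pulse(self._make_segments(3), 125)
        assert len(rep.samples) == PULSE_LENGTH
        assert rep.samples.min() == 0.0
        assert rep.samples.max() == 1.0

    def test_flat_template_raises(self):
        segs = [PulseSegment(np.full(100, 2.0), 0, 0.8)] * 4
        with pytest.raises(NormalizationError):
            representative_pulse(segs, 125)


class TestPreprocessRecording:
    def test_clean_recording_counts(self, clean_recording):
        pulse, log = preprocess_recording(clean_recording.signal, 125)
        n_beats = clean_recording.log.n_beats
        # all interior beats survive; at most the two edge segments drop
        assert n_beats - 3 <= pulse.n_segments_used <= n_beats
        counts = log.counts
        assert counts["onsets"] >= counts["segments"] >= counts["retained"] \
            >= counts["used"]

    def test_template_recovery(self, clean_recording, clean_spec):
        pulse, _ = preprocess_recording(clean_recording.signal, 125)
        truth = synth_pulse(clean_recording.ground_truth_params,
                            clean_spec.mean_ppi, 125)
        t144 = _resample_cubic(truth, PULSE_LENGTH)
        t144 = (t144 - t144.min()) / (t144.max() - t144.min())
        assert np.corrcoef(pulse.samples, t144)[0, 1] >= 0.99

    def test_pulseless_recording_unusable(self):
        sig = np.full(4000, 10.0)  # no upstrokes at all
        with pytest.raises(UnusableRecordingError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preprocess_recording(sig, 125)

    def test_outputs_finite_and_normalized(self, small_pulse_dataset):
        X, _, _ = small_pulse_dataset
        assert np.all(np.isfinite(X))
        assert X.min() >= 0.0 and X.max() <= 1.0
        assert np.allclose(X.min(axis=1), 0.0)
        assert np.allclose(X.max(axis=1), 1.0)
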