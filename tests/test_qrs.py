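"""QRS detection: derivative energy, thresholding and detection quality."""

import numpy as np
import pytest

from swmar.qrs import (EnergyFrameSeries, detect_qrs, estimate_qrs_threshold,
                       frame_energy, second_derivative)
from swmar.preprocess import bandpass_ecg
from swmar.synthetic import generate_ecg
from swmar.evaluate import score_detections

FS = 250.0


class TestSecondDerivative:
    def test_parabola_gives_constant_two(self):
        k = np.arange(20.0)
        assert np.allclose(second_derivative(k**2)[1:-1], 2.0)

    def test_ramp_gives_zero(self):
        assert np.allclose(second_derivative(np.arange(20.0))[1:-1], 0.0)

    def test_impulse_stencil(self):
        x = np.zeros(9)
        x[4] = 1.0
        d2 = second_derivative(x)
        assert d2[3] == 1.0 and d2[4] == -2.0 and d2[5] == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            second_derivative(np.zeros(2))


class TestFrameEnergy:
    def test_single_frame_of_ones(self):
        e = frame_energy(np.ones(8), FS, win_ms=32, shift_ms=16)
        assert e.energies.tolist() == [8.0]

    def test_zeros_give_zero_energy(self):
        assert np.all(frame_energy(np.zeros(40), FS).energies == 0.0)

    def test_sum_of_squares_per_frame(self):
        # 8-sample window, 4-sample shift at 250 Hz
        x = np.arange(1.0, 13.0)
        e = frame_energy(x, FS, win_ms=32, shift_ms=16)
        assert e.frame_len == 8 and e.frame_shift == 4
        # direct oracle: sum(1..8 squared) = 204, sum(5..12 squared) = 620
        assert e.energies.tolist() == [204.0, 620.0]

    def test_nominal_ms_round_to_integer_frames(self):
        e = frame_energy(np.zeros(100), FS)  # 30/15 ms nominal
        assert e.frame_len == 8 and e.frame_shift == 4

    def test_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            frame_energy(np.zeros(4), FS, win_ms=32, shift_ms=16)


def _energy(values):
    return EnergyFrameSeries(np.asarray(values, float), frame_len=8,
                             frame_shift=4, fs=FS)


class TestThreshold:
    def test_flat_energy_threshold_equals_value(self):
        thr = estimate_qrs_threshold(_energy(np.full(200, 7.0)))
        assert thr.threshold == 7.0

    def test_alternating_frames_midpoint(self):
        e = np.tile([0.0, 10.0], 100)
        thr = estimate_qrs_threshold(_energy(e))
        assert thr.lm_median == 10.0 and thr.lmin_median == 0.0
        assert thr.threshold == 5.0

    def test_threshold_between_medians(self, rng):
        thr = estimate_qrs_threshold(_energy(rng.random(500)))
        assert thr.lm_median >= thr.threshold >= thr.lmin_median

    def test_separates_qrs_from_baseline_frames(self):
        ecg, truth = generate_ecg(60, seed=1, noise_snr_db=None)
        x = bandpass_ecg(ecg, FS)
        energy = frame_energy(second_derivative(x), FS)
        thr = estimate_qrs_threshold(energy).threshold
        starts = energy.starts
        r_peaks = truth.intervals.mean(axis=1)  # R is central in the complex
        for r in r_peaks:  # every beat has an above-threshold frame at its R
            covers = (starts <= r) & (r < starts + energy.frame_len)
            assert energy.energies[covers].max() > thr
        qrs_mask = truth.dilate(0.04).to_mask(len(x))
        baseline = ~np.array([qrs_mask[s:s + energy.frame_len].any()
                              for s in starts])
        assert thr > np.quantile(energy.energies[baseline], 0.95)


class TestDetect:
    def test_zero_signal_gives_no_detections(self):
        assert len(detect_qrs(np.zeros(5000), FS)) == 0

    def test_clean_rhythm_fully_detected(self):
        ecg, truth = generate_ecg(60, mean_rr_s=1.5, rr_jitter=0.0,
                                  noise_snr_db=None, seed=3)
        det = detect_qrs(bandpass_ecg(ecg, FS), FS)
        assert abs(len(det) - 40) <= 1
        r_peaks = truth.intervals.mean(axis=1)
        for r in r_peaks:
            assert np.any((det.intervals[:, 0] <= r) & (r < det.intervals[:, 1]))

    def test_detected_intervals_sorted_disjoint(self, rng):
        ecg, _ = generate_ecg(60, noise_snr_db=15, seed=9)
        det = detect_qrs(bandpass_ecg(ecg, FS), FS)
        assert np.all(np.diff(det.intervals[:, 0]) > 0)
        assert np.all(det.intervals[1:, 0] >= det.intervals[:-1, 1])

    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_amplitude_scale_invariance(self, c):
        ecg, _ = generate_ecg(30, noise_snr_db=20, seed=5)
        x = bandpass_ecg(ecg, FS)
        assert np.array_equal(detect_qrs(x, FS).intervals,
                              detect_qrs(c * x, FS).intervals)

    def test_noisy_sensitivity_and_precision(self):
        for seed in range(5):
            ecg, truth = generate_ecg(60, noise_snr_db=20, seed=seed)
            det = detect_qrs(bandpass_ecg(ecg, FS), FS)
            sens, prec = score_detections(det, truth, tol_s=0.075)
            assert sens >= 0.95 and prec >= 0.95

    def test_onset_marker_accuracy(self):
        """Median |A - true QRS onset| stays below 40 ms across seeds."""
        medians = []
        for seed in range(20):
            ecg, truth = generate_ecg(60, noise_snr_db=20, seed=seed)
            det = detect_qrs(bandpass_ecg(ecg, FS), FS)
            errs = [np.min(np.abs(det.intervals[:, 0] - ts)) / FS
                    for ts, _ in truth.intervals]
            medians.append(np.median(errs))
        assert np.median(medians) <= 0.040
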