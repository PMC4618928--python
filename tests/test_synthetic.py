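"""Generator bookkeeping: determinism, ground-truth consistency, magnitudes."""

import numpy as np
import pytest

from swmar.preprocess import acceleration_module, upsample_accel
from swmar.synthetic import (generate_accel, generate_ecg, generate_truth,
                             inject_artifacts, make_study)

FS = 250.0


class TestGenerateEcg:
    def test_regular_rhythm_count_and_spacing(self):
        ecg, qrs = generate_ecg(60, mean_rr_s=1.5, rr_jitter=0.0, seed=0)
        assert len(qrs) == 40
        r_gaps = np.diff(qrs.intervals[:, 0] + qrs.intervals[:, 1])  # 2x center
        assert np.all(np.abs(r_gaps / 2 - 375) <= 1)
        peaks = np.flatnonzero(ecg > 0.9 * ecg.max())
        assert np.all(np.diff(np.unique(peaks // 375)) == 1)

    def test_zero_amplitudes_flat_but_annotated(self):
        morph = {k: (0.0, off, sig) for k, (a, off, sig) in
                 __import__("swmar.synthetic", fromlist=["DEFAULT_MORPHOLOGY"]
                            ).DEFAULT_MORPHOLOGY.items()}
        ecg, qrs = generate_ecg(60, mean_rr_s=1.5, rr_jitter=0.0,
                                morphology=morph, seed=0)
        assert np.all(ecg == 0.0)
        assert len(qrs) == 40

    def test_deterministic_under_seed(self):
        a = generate_ecg(30, noise_snr_db=20, seed=77)
        b = generate_ecg(30, noise_snr_db=20, seed=77)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1].intervals, b[1].intervals)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_ecg(2.0, mean_rr_s=1.5)


class TestGenerateAccel:
    def test_no_bursts_near_constant_module(self):
        ax, ay, az, bursts = generate_accel(60, n_bursts=0, seed=1)
        assert len(bursts) == 0
        mod = acceleration_module(ax, ay, az)
        assert mod.std() < 0.02 * mod.mean()

    def test_single_burst_interval_length(self):
        _, _, _, bursts = generate_accel(60, n_bursts=1, burst_len_s=2.0, seed=2)
        assert len(bursts) == 1
        s, e = bursts.intervals[0]
        assert e - s == 50  # 2 s at 25 Hz

    def test_reproducible_placement(self):
        a = generate_accel(120, n_bursts=5, seed=9)
        b = generate_accel(120, n_bursts=5, seed=9)
        assert np.array_equal(a[3].intervals, b[3].intervals)
        assert np.array_equal(a[0], b[0])

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValueError):
            generate_accel(20, n_bursts=10, burst_len_s=5.0)


def _module_for(truth):
    rec = truth.recording
    comps = (upsample_accel(c, rec.fs_acc, rec.fs_ecg)
             for c in (rec.acc_x, rec.acc_y, rec.acc_z))
    return acceleration_module(*comps)[: len(truth.clean_ecg)]


class TestInjectArtifacts:
    def test_zero_gain_is_identity(self):
        truth = generate_truth(60, seed=0)
        mod = _module_for(truth)
        obs, art = inject_artifacts(truth.clean_ecg, mod, truth.burst_truth,
                                    gain=0.0, seed=0)
        assert np.array_equal(obs, truth.clean_ecg)
        assert np.all(art == 0.0)

    def test_observed_is_clean_plus_artifact(self):
        for seed in range(3):
            truth = generate_truth(60, seed=seed)
            assert np.array_equal(truth.recording.ecg,
                                  truth.clean_ecg + truth.artifact)

    def test_support_inside_dilated_bursts(self):
        for seed in range(5):
            truth = generate_truth(60, seed=seed)
            n = len(truth.artifact)
            win = truth.burst_truth.rescale(FS).dilate(0.5, n_samples=n)
            assert np.all(truth.artifact[~win.to_mask(n)] == 0.0)

    def test_artifact_dominates_corrupted_segments(self):
        """At default gains the in-burst artifact RMS is at least three times
        the clean-ECG RMS, so corrupted stretches are visually dominated."""
        for seed in range(5):
            truth = generate_truth(120, seed=seed)
            n = len(truth.artifact)
            m = truth.burst_truth.rescale(FS).dilate(0.5, n_samples=n).to_mask(n)
            ratio = (np.sqrt(np.mean(truth.artifact[m] ** 2))
                     / np.sqrt(np.mean(truth.clean_ecg ** 2)))
            assert ratio >= 3.0

    def test_unknown_kind_rejected(self):
        truth = generate_truth(60, seed=0)
        with pytest.raises(ValueError):
            inject_artifacts(truth.clean_ecg, _module_for(truth),
                             truth.burst_truth, kinds=("hum",))


class TestMakeStudy:
    def test_reproducible_suite(self):
        a = make_study(n_subjects=2, duration_s=120, master_seed=5)
        b = make_study(n_subjects=2, duration_s=120, master_seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.recording.ecg, tb.recording.ecg)
            assert ta.params == tb.params

    def test_single_subject(self):
        suite = make_study(n_subjects=1, duration_s=120, master_seed=3)
        assert len(suite) == 1
        assert suite[0].recording.duration_s == pytest.approx(120.0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            make_study(n_subjects=0)
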