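"""Motion detection on the acceleration module.

Time intervals where the movement amplitude is strong enough to induce ECG
artifacts are found with a robust amplitude threshold

    T = median(p) + 1.4826 * MAD(p)

where ``p`` is the rectified, mean-subtracted acceleration module (the mean
subtraction removes the gravity component, making detection offset-invariant)
and 1.4826*MAD is the usual robust estimate of the standard deviation.
Raw above-threshold runs are dilated by ``pad_s`` on both sides because the
electrode-potential disturbance outlasts the mechanical burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IntervalSet

__all__ = ["motion_threshold", "detect_motion", "MotionThreshold"]


@dataclass
class MotionThreshold:
    t_value: float
    median_acc: float
    mad_acc: float


def motion_threshold(acc: np.ndarray) -> MotionThreshold:
    """Robust motion threshold ``median + 1.4826*MAD`` of the whole record."""
    acc = np.asarray(acc, dtype=float)
    if acc.size == 0:
        raise ValueError("empty acceleration series")
    med = float(np.median(acc))
    mad = float(np.median(np.abs(acc - med)))
    return MotionThreshold(t_value=med + 1.4826 * mad, median_acc=med, mad_acc=mad)


def detect_motion(acc: np.ndarray, fs: float, pad_s: float = 0.5,
                  smooth_s: float = 0.5, min_run_s: float = 0.2,
                  on_preprocessed: bool = True) -> IntervalSet:
    """Intervals of the acceleration module able to generate movement artifacts.

    The module is mean-subtracted and rectified, then envelope-smoothed with a
    ``smooth_s`` moving average (rectify + low-pass is the classic envelope
    detector; it keeps a burst contiguous across the zero crossings of its
    oscillation).  Samples exceeding the robust threshold form raw intervals;
    runs shorter than ``min_run_s`` are discarded as sensor-noise blips, and
    the survivors are dilated by ``pad_s`` seconds and merged.
    ``on_preprocessed=False`` computes the threshold on the raw module instead
    (the comparison is always made on the series the threshold was computed
    from, so either variant is self-consistent).
    """
    acc = np.asarray(acc, dtype=float)
    series = np.abs(acc - acc.mean()) if on_preprocessed else acc.copy()
    if smooth_s > 0:
        k = max(1, int(round(smooth_s * fs)))
        series = np.convolve(series, np.ones(k) / k, mode="same")
    t = motion_threshold(series).t_value
    raw = IntervalSet.from_mask(series > t, fs=fs, label="motion")
    min_run = int(round(min_run_s * fs))
    keep = [iv for iv in raw.intervals if iv[1] - iv[0] >= min_run]
    raw = IntervalSet(np.array(keep, dtype=np.int64).reshape(-1, 2), fs=fs,
                      label="motion", n_samples=len(acc))
    return raw.dilate(pad_s, n_samples=len(acc))
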