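"""Preprocessing: ECG band-limiting and accelerometer conditioning.

The ECG is band-passed 0.5-40 Hz with a zero-phase Butterworth filter (order 4,
applied forward-backward).  The three accelerometer components are upsampled
from 25 Hz to the ECG rate by linear interpolation and combined into the
acceleration module, the pointwise Euclidean norm of the three axes — the
single motion summary every downstream detector consumes.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .io import Recording

__all__ = ["bandpass_ecg", "upsample_accel", "acceleration_module", "preprocess"]


def design_bandpass(fs: float, low: float = 0.5, high: float = 40.0,
                    order: int = 4) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass used for the ECG."""
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} must exceed twice the upper edge {high} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_ecg(ecg: np.ndarray, fs: float, low: float = 0.5, high: float = 40.0,
                 order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.5-40 Hz).

    Forward-backward application doubles the effective order and cancels the
    phase response.  Edges are handled by reflecting up to 3 s of signal, which
    suppresses startup transients on hour-long records and short fixtures
    alike.  Signals not longer than three times the filter order are rejected.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) <= 3 * order:
        raise ValueError(f"signal of {len(ecg)} samples too short to filter")
    sos = design_bandpass(fs, low, high, order)
    padlen = min(int(round(3 * fs)), len(ecg) - 1)
    return signal.sosfiltfilt(sos, ecg, padlen=padlen)


def upsample_accel(component: np.ndarray, fs_in: float = 25.0,
                   fs_out: float = 250.0) -> np.ndarray:
    """Linear interpolation of one accelerometer component to the ECG rate.

    The rate ratio must be an integer ``r``; input samples are preserved at
    indices ``k*r`` and the tail is padded with the edge value so the output
    has exactly ``n_in * r`` samples.
    """
    component = np.asarray(component, dtype=float)
    ratio = fs_out / fs_in
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9 or r < 1:
        raise ValueError(f"fs_out/fs_in = {ratio} is not an integer ratio")
    n = len(component)
    if n == 0:
        raise ValueError("empty accelerometer series")
    grid = np.arange((n - 1) * r + 1) / r
    out = np.interp(grid, np.arange(n), component)
    return np.concatenate([out, np.full(n * r - len(out), component[-1])])


def acceleration_module(acc_x: np.ndarray, acc_y: np.ndarray,
                        acc_z: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean norm of the three accelerometer components."""
    acc_x, acc_y, acc_z = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not (len(acc_x) == len(acc_y) == len(acc_z)):
        raise ValueError("accelerometer components differ in length")
    return np.sqrt(acc_x**2 + acc_y**2 + acc_z**2)


def preprocess(rec: Recording, low: float = 0.5, high: float = 40.0,
               order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Run the full preprocessing stage on a recording.

    Returns ``(ecg_filtered, acc_module)`` with both series at ``rec.fs_ecg``.
    Components are upsampled first, then combined into the module.
    """
    ecg_f = bandpass_ecg(rec.ecg, rec.fs_ecg, low=low, high=high, order=order)
    comps = [upsample_accel(c, rec.fs_acc, rec.fs_ecg)
             for c in (rec.acc_x, rec.acc_y, rec.acc_z)]
    acc = acceleration_module(*comps)
    n = len(ecg_f)
    if len(acc) < n:  # sub-sample duration slack between the two rates
        acc = np.concatenate([acc, np.full(n - len(acc), acc[-1])])
    return ecg_f, acc[:n]
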