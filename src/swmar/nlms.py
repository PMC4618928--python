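"""Normalized LMS adaptive noise cancellation (the comparator method).

The primary input is the corrupted ECG ``x = s + n0``; the reference input is
a signal correlated with the interference ``n0`` but not with the cardiac
signal ``s`` — here the mean-subtracted acceleration module.  An FIR filter
driven by the reference is adapted to minimize the output power ``E[z^2]``
with ``z = x - y``; since ``s`` is uncorrelated with the reference, minimizing
``E[z^2]`` minimizes ``E[(n0 - y)^2]`` and ``z`` converges to the best linear
estimate of ``s``.  The update is the standard power-normalized step

    w <- w + mu / (eps + ||u||^2) * z(n) * u(n)

with zero-initialized weights.
"""

from __future__ import annotations

import numpy as np

from .io import Recording
from .preprocess import preprocess

__all__ = ["nlms_cancel", "nlms_clean_recording"]


def nlms_cancel(primary: np.ndarray, reference: np.ndarray, order: int = 32,
                mu: float = 0.5, eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive cancellation of reference-correlated interference.

    Returns ``(z, y)``: the cleaned output (error signal) and the filter
    output.  ``u(n)`` holds the most recent ``order`` reference samples.
    """
    primary = np.asarray(primary, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(primary) != len(reference):
        raise ValueError("primary and reference must have equal lengths")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if not 0.0 <= mu < 2.0:
        raise ValueError("step size mu must lie in [0, 2)")
    if eps <= 0:
        raise ValueError("regularizer eps must be positive")

    n = len(primary)
    w = np.zeros(order)
    y = np.zeros(n)
    z = np.zeros(n)
    buf = np.zeros(order)  # buf[0] = current reference sample
    for i in range(n):
        buf[1:] = buf[:-1]
        buf[0] = reference[i]
        y[i] = w @ buf
        z[i] = primary[i] - y[i]
        norm = buf @ buf
        w += (mu / (eps + norm)) * z[i] * buf
    return z, y


def nlms_clean_recording(rec: Recording, order: int = 32, mu: float = 0.1,
                         eps_rel: float = 0.1, low: float = 0.5,
                         high: float = 40.0, filter_order: int = 4) -> np.ndarray:
    """Band-pass the ECG and cancel motion-correlated interference.

    The reference is the acceleration module upsampled to the ECG rate and
    mean-subtracted (the constant gravity share carries no information).
    Because that reference is intermittent — near-silent between movement
    bursts — the regularizer is scaled to its average power
    (``eps = eps_rel * order * mean(ref^2)``) and the step is kept small;
    otherwise the normalized update blows up on the quiet segments and the
    filter chases the ECG itself.
    """
    ecg_f, acc = preprocess(rec, low=low, high=high, order=filter_order)
    reference = acc - acc.mean()
    # flush rounding residue of the mean subtraction so a constant
    # accelerometer yields a truly inert (zero) reference
    scale = max(1.0, float(np.max(np.abs(acc))))
    reference[np.abs(reference) < 1e-12 * scale] = 0.0
    eps = max(eps_rel * order * float(np.mean(reference ** 2)), 1e-12)
    z, _ = nlms_cancel(ecg_f, reference, order=order, mu=mu, eps=eps)
    return z
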