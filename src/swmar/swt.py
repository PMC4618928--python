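"""Stationary (undecimated, à trous) wavelet transform with exact inverse.

Unlike the decimated DWT, the SWT keeps every level at the full signal length,
which makes it shift-invariant: the coefficients of a delayed signal are the
delayed coefficients of the original.  At level ``j`` the orthonormal filter
pair is upsampled by inserting ``2**(j-1) - 1`` zeros between taps and applied
by circular convolution with no decimation.  The input is padded to the next
multiple of ``2**level`` by edge replication so the dyadic wrap is consistent;
the pad is trimmed again on reconstruction.

Level 1 is the finest scale (fastest-changing content, i.e. the QRS complexes
at 250 Hz); higher levels carry progressively slower content (P and T waves,
baseline).  The default wavelet is the two-tap Haar pair, which is exactly
invertible with no edge effects; any orthonormal pair known to PyWavelets can
be substituted.

Conventions (fixed here, shared by the brute-force oracle in the test-suite):
square-root-of-two-normalized filters at every level, anti-causal indexing
``A_{j}[k] = sum_l h[l] A_{j-1}[(k + 2**(j-1) l) mod N]``, circular wrap.
For any paraunitary pair the adjoint relation ``(H*H + G*G)/2 = I`` gives the
exact inverse used by :func:`swt_reconstruct`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["haar_filters", "wavelet_filters", "swt_decompose",
           "swt_reconstruct", "SwtCoefficients"]

_SQRT2 = np.sqrt(2.0)


def haar_filters() -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal Haar pair: lowpass (1,1)/sqrt(2), highpass (1,-1)/sqrt(2)."""
    low = np.array([1.0, 1.0]) / _SQRT2
    high = np.array([1.0, -1.0]) / _SQRT2
    return low, high


def wavelet_filters(name: str = "haar") -> tuple[np.ndarray, np.ndarray]:
    """Resolve a wavelet name to an orthonormal (lowpass, highpass) pair."""
    if name.lower() in ("haar", "db1"):
        return haar_filters()
    import pywt

    w = pywt.Wavelet(name)
    if not w.orthogonal:
        raise ValueError(f"wavelet {name!r} is not orthogonal")
    return np.asarray(w.dec_lo, float), np.asarray(w.dec_hi, float)


@dataclass
class SwtCoefficients:
    """Redundant wavelet decomposition of one signal.

    ``details[0]`` is level 1 (finest); every series, including the final
    approximation, has the padded signal length. ``original_length`` records
    how many leading samples belong to the unpadded input.
    """

    details: list[np.ndarray]
    approximation: np.ndarray
    level: int
    wavelet: str
    original_length: int

    @property
    def padded_length(self) -> int:
        return len(self.approximation)

    def copy(self) -> "SwtCoefficients":
        return SwtCoefficients([d.copy() for d in self.details],
                               self.approximation.copy(), self.level,
                               self.wavelet, self.original_length)


def _analysis_step(a: np.ndarray, taps: np.ndarray, dilation: int) -> np.ndarray:
    out = np.zeros_like(a)
    for l, t in enumerate(taps):
        out += t * np.roll(a, -dilation * l)
    return out


def _synthesis_step(c: np.ndarray, taps: np.ndarray, dilation: int) -> np.ndarray:
    out = np.zeros_like(c)
    for l, t in enumerate(taps):
        out += t * np.roll(c, dilation * l)
    return out


def swt_decompose(x: np.ndarray, level: int = 5,
                  wavelet: str = "haar") -> SwtCoefficients:
    """Decompose ``x`` into ``level`` detail series plus one approximation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot decompose an empty signal")
    if level < 1:
        raise ValueError("level must be >= 1")
    low, high = wavelet_filters(wavelet)
    n0 = len(x)
    block = 2 ** level
    n = int(np.ceil(n0 / block)) * block
    a = np.concatenate([x, np.full(n - n0, x[-1])])
    details: list[np.ndarray] = []
    for j in range(1, level + 1):
        d = 2 ** (j - 1)
        details.append(_analysis_step(a, high, d))
        a = _analysis_step(a, low, d)
    return SwtCoefficients(details=details, approximation=a, level=level,
                           wavelet=wavelet, original_length=n0)


def swt_reconstruct(coeffs: SwtCoefficients) -> np.ndarray:
    """Exact inverse of :func:`swt_decompose`, trimmed to the original length."""
    low, high = wavelet_filters(coeffs.wavelet)
    n = coeffs.padded_length
    if len(coeffs.details) != coeffs.level:
        raise ValueError("detail levels inconsistent with declared level")
    if any(len(d) != n for d in coeffs.details):
        raise ValueError("coefficient series have inconsistent lengths")
    if n % (2 ** coeffs.level) != 0:
        raise ValueError("padded length is not a multiple of 2**level")
    a = coeffs.approximation
    for j in range(coeffs.level, 0, -1):
        d = 2 ** (j - 1)
        a = 0.5 * (_synthesis_step(a, low, d)
                   + _synthesis_step(coeffs.details[j - 1], high, d))
    return a[: coeffs.original_length]
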