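"""Artifact removal: robust per-level thresholding of motion-gated SWT coefficients.

The movement-artifact estimate is built in the wavelet domain.  After the
motion detector has marked the segments able to generate artifacts, the
coefficients of the first three (finest) decomposition levels are zeroed
outside those segments — outside motion the fine scales are pure cardiac
content.  For every detail level and the approximation, maxima and minima of
the (gated) coefficients are then collected over non-overlapping 1 s frames,
and robust statistics of those two distributions give per-level bounds

    M_j = median(maxima) + 1.4826 * MAD(maxima)
    m_j = median(minima) - 1.4826 * MAD(minima)

Coefficients above ``M_j`` or below ``m_j`` inside motion segments are
attributed to the artifact; samples inside detected QRS complexes are
protected at the fine levels so the large ventricular deflection is not
mistaken for noise.  The inverse transform of the artifact coefficients is a
time-domain artifact waveform, which is subtracted from the band-passed ECG.
Outside motion segments the output is bit-identical to its input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np

from .io import IntervalSet, Recording
from .motion import detect_motion
from .preprocess import preprocess
from .qrs import detect_qrs
from .swt import SwtCoefficients, swt_decompose, swt_reconstruct

__all__ = ["robust_stats", "zero_artifact_free", "frame_extrema",
           "level_thresholds", "estimate_artifact", "remove_artifacts",
           "LevelThresholds", "ArtifactEstimate", "SwmarConfig", "SwmarResult"]


def robust_stats(x: np.ndarray) -> tuple[float, float]:
    """Robust (mean, SD) estimate: ``(median(x), 1.4826 * MAD(x))``.

    The 1.4826 factor makes the MAD a consistent estimator of the standard
    deviation for Gaussian data.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty value series")
    mu = float(np.median(x))
    sigma = 1.4826 * float(np.median(np.abs(x - mu)))
    return mu, sigma


def zero_artifact_free(coeffs: SwtCoefficients, motion: IntervalSet,
                       levels: tuple[int, ...] = (1, 2, 3)) -> SwtCoefficients:
    """Zero the listed detail levels outside every motion interval.

    Motion intervals must live on the same (ECG-rate) time base as the
    coefficients; the pad region beyond the original length is treated as
    artifact-free as well.
    """
    out = coeffs.copy()
    for lv in levels:
        if not 1 <= lv <= coeffs.level:
            raise ValueError(f"level {lv} outside 1..{coeffs.level}")
    mask = np.zeros(coeffs.padded_length, dtype=bool)
    mask[: coeffs.original_length] = motion.to_mask(coeffs.original_length)
    for lv in levels:
        out.details[lv - 1][~mask] = 0.0
    return out


def frame_extrema(coeff: np.ndarray, fs: float,
                  frame_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (max, min) over non-overlapping ``frame_s`` frames.

    The trailing partial frame is dropped.
    """
    coeff = np.asarray(coeff, dtype=float)
    flen = int(round(frame_s * fs))
    n_frames = len(coeff) // flen
    if n_frames == 0:
        raise ValueError("series shorter than one frame")
    frames = coeff[: n_frames * flen].reshape(n_frames, flen)
    return frames.max(axis=1), frames.min(axis=1)


@dataclass
class LevelBounds:
    """Upper/lower robust bounds of one coefficient series."""

    M: float
    m: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float


@dataclass
class LevelThresholds:
    """Per-level bounds for every detail series plus the approximation."""

    details: list[LevelBounds]
    approximation: LevelBounds


def _bounds(coeff: np.ndarray, fs: float, frame_s: float,
            keep: np.ndarray | None) -> LevelBounds:
    maxima, minima = frame_extrema(coeff, fs, frame_s)
    if keep is not None:
        maxima, minima = maxima[keep], minima[keep]
    mu1, s1 = robust_stats(maxima)
    mu2, s2 = robust_stats(minima)
    return LevelBounds(M=mu1 + s1, m=mu2 - s2, mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2)


def level_thresholds(coeffs: SwtCoefficients, fs: float, frame_s: float = 1.0,
                     exclude: IntervalSet | None = None,
                     min_frames: int = 10) -> LevelThresholds:
    """Robust artifact bounds for each level of an (already gated) decomposition.

    The bounds are meant to describe the range of artifact-free cardiac
    coefficients, so when ``exclude`` (normally the motion intervals) is
    given, frames overlapping it are left out of the statistics — otherwise a
    record that moves more than half the time would have its bounds set by
    the very artifacts they are supposed to detect.  If fewer than
    ``min_frames`` clean frames remain, all frames are used.
    """
    n0 = coeffs.original_length
    keep = None
    if exclude is not None:
        flen = int(round(frame_s * fs))
        n_frames = n0 // flen
        mask = exclude.to_mask(n0)
        frame_hit = mask[: n_frames * flen].reshape(n_frames, flen).any(axis=1)
        if np.count_nonzero(~frame_hit) >= min_frames:
            keep = ~frame_hit
    details = [_bounds(d[:n0], fs, frame_s, keep) for d in coeffs.details]
    approx = _bounds(coeffs.approximation[:n0], fs, frame_s, keep)
    return LevelThresholds(details=details, approximation=approx)


@dataclass
class ArtifactEstimate:
    """Reconstructed movement-artifact waveform and its provenance."""

    artifact_signal: np.ndarray
    gated_coeffs: SwtCoefficients
    thresholds: LevelThresholds
    motion: IntervalSet
    qrs: IntervalSet | None


def _artifact_level(c: np.ndarray, bounds: LevelBounds, motion_mask: np.ndarray,
                    mode: str) -> np.ndarray:
    art = np.zeros_like(c)
    over = motion_mask & (c > bounds.M)
    under = motion_mask & (c < bounds.m)
    if mode == "full":
        art[over] = c[over]
        art[under] = c[under]
    elif mode == "exceedance":
        art[over] = c[over] - bounds.M
        art[under] = c[under] - bounds.m
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return art


def estimate_artifact(coeffs: SwtCoefficients, thresholds: LevelThresholds,
                      motion: IntervalSet, qrs: IntervalSet | None = None,
                      mode: str = "full", qrs_protect: bool = True,
                      protect_levels: tuple[int, ...] = (1, 2, 3),
                      threshold_approx: bool = True) -> ArtifactEstimate:
    """Build the artifact decomposition and reconstruct its time-domain waveform.

    Per level, coefficients are attributed to the artifact only inside motion
    intervals and only beyond the ``[m_j, M_j]`` band.  ``mode='full'``
    (default) attributes the whole out-of-band coefficient to the artifact;
    ``mode='exceedance'`` takes only the beyond-threshold excess ``c - M_j`` /
    ``c - m_j``, which preserves the in-band share but leaves the clipped
    remnant of large slow excursions.  With ``qrs_protect`` the fine levels in
    ``protect_levels`` contribute nothing inside detected QRS complexes.  The
    reconstructed waveform is gated to the motion support so it is identically
    zero outside motion intervals.
    """
    n0 = coeffs.original_length
    npad = coeffs.padded_length
    motion_mask = np.zeros(npad, dtype=bool)
    motion_mask[:n0] = motion.to_mask(n0)
    qrs_mask = np.zeros(npad, dtype=bool)
    if qrs is not None and qrs_protect:
        qrs_mask[:n0] = qrs.to_mask(n0)

    art = coeffs.copy()
    for j in range(1, coeffs.level + 1):
        a = _artifact_level(coeffs.details[j - 1], thresholds.details[j - 1],
                            motion_mask, mode)
        if j in protect_levels:
            a[qrs_mask] = 0.0
        art.details[j - 1] = a
    if threshold_approx:
        art.approximation = _artifact_level(coeffs.approximation,
                                            thresholds.approximation,
                                            motion_mask, mode)
    else:
        art.approximation = np.zeros_like(coeffs.approximation)

    signal = swt_reconstruct(art)
    signal[~motion_mask[:n0]] = 0.0
    return ArtifactEstimate(artifact_signal=signal, gated_coeffs=art,
                            thresholds=thresholds, motion=motion, qrs=qrs)


@dataclass
class SwmarConfig:
    """Tunable parameters of the full removal pipeline (CLI/config mirror)."""

    filter_low_hz: float = 0.5
    filter_high_hz: float = 40.0
    filter_order: int = 4
    qrs_win_ms: float = 30.0
    qrs_shift_ms: float = 15.0
    qrs_interval_s: float = 1.5
    qrs_merge_gap_ms: float = 100.0
    motion_pad_s: float = 0.5
    motion_on_preprocessed: bool = True
    swt_level: int = 5
    swt_wavelet: str = "haar"
    zero_levels: tuple[int, ...] = (1, 2, 3)
    frame_s: float = 1.0
    mode: str = "full"
    qrs_protect: bool = True
    threshold_approx: bool = True
    threshold_frames: str = "clean"  # "clean": stats from motion-free frames

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SwmarConfig":
        d = dict(d)
        if "zero_levels" in d:
            d["zero_levels"] = tuple(d["zero_levels"])
        return cls(**d)


class SwmarResult(NamedTuple):
    cleaned: np.ndarray
    artifact: ArtifactEstimate
    motion: IntervalSet
    qrs: IntervalSet


def remove_artifacts(rec: Recording, config: SwmarConfig | None = None) -> SwmarResult:
    """Run the full movement-artifact removal pipeline on a recording.

    Preprocessing, QRS and motion detection, SWT decomposition, per-level
    robust thresholding and artifact reconstruction, then subtraction of the
    artifact waveform from the band-passed ECG.  Wherever the artifact
    estimate is zero (in particular everywhere outside motion intervals) the
    cleaned signal equals the band-passed ECG exactly.
    """
    cfg = config or SwmarConfig()
    ecg_f, acc = preprocess(rec, low=cfg.filter_low_hz, high=cfg.filter_high_hz,
                            order=cfg.filter_order)
    qrs = detect_qrs(ecg_f, rec.fs_ecg, win_ms=cfg.qrs_win_ms,
                     shift_ms=cfg.qrs_shift_ms, interval_s=cfg.qrs_interval_s,
                     merge_gap_ms=cfg.qrs_merge_gap_ms)
    motion = detect_motion(acc, rec.fs_ecg, pad_s=cfg.motion_pad_s,
                           on_preprocessed=cfg.motion_on_preprocessed)
    coeffs = swt_decompose(ecg_f, level=cfg.swt_level, wavelet=cfg.swt_wavelet)
    gated = zero_artifact_free(coeffs, motion, levels=cfg.zero_levels)
    thresholds = level_thresholds(
        gated, rec.fs_ecg, frame_s=cfg.frame_s,
        exclude=motion if cfg.threshold_frames == "clean" else None)
    artifact = estimate_artifact(gated, thresholds, motion, qrs=qrs,
                                 mode=cfg.mode, qrs_protect=cfg.qrs_protect,
                                 protect_levels=cfg.zero_levels,
                                 threshold_approx=cfg.threshold_approx)
    cleaned = ecg_f - artifact.artifact_signal
    zero = artifact.artifact_signal == 0.0
    cleaned[zero] = ecg_f[zero]  # bit-exact passthrough where nothing was removed
    return SwmarResult(cleaned=cleaned, artifact=artifact, motion=motion, qrs=qrs)
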