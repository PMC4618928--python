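# Methods

This note documents the signal model, the algorithmic choices and the known
limitations of the `swmar` toolkit. Everything quantitative stated here is
computed by the test-suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Problem setting

A single-lead ECG (250 Hz) is recorded together with a triaxial accelerometer
(25 Hz) on one device, so the two channels share a time base and no lag
estimation is needed. Movement artifacts (MAs) arise from skin stretch under
the electrodes: a mechanical burst perturbs the electrode half-cell potential,
producing low-frequency baseline excursions, step-like offsets that outlast
the burst, and short high-amplitude transients. Their spectrum overlaps the
ECG band, so removal must be *time-localized* (only where motion occurred) and
*scale-selective* (only components too large to be cardiac).

## Preprocessing

- ECG: zero-phase Butterworth band-pass 0.5–40 Hz, order 4 applied
  forward–backward (effective order 8). Edges are handled by reflecting up to
  3 s of signal, which keeps transients negligible on both hour-long records
  and short test fixtures. Config keys `filter.low_hz`, `filter.high_hz`,
  `filter.order`.
- Accelerometer: each component is linearly interpolated from 25 Hz to
  250 Hz (knots preserved exactly; tail padded by the edge value), then
  combined into the acceleration module, the pointwise Euclidean norm.
  Components are upsampled first and combined second; the module is
  rotation-invariant, so electrode-belt orientation does not matter. No
  band-limiting is applied to the accelerometer.

## QRS detection

The second central difference of the band-passed ECG suppresses slow waves
and accentuates the QRS. Its energy is summed over 30 ms frames shifted by
15 ms; at 250 Hz these round to 8 samples with a 4-sample shift, which keeps
the 50% overlap exact. In each non-overlapping 1.5 s interval — the longest
mean RR interval expected for a resting horse, so each interval contains at
least one beat — the maximum (LM) and minimum (Lm) frame energy are
collected; the detection threshold is the midpoint of `median(LM)` and
`median(Lm)` (the median of a two-value set). Runs of above-threshold frames
become QRS intervals `[A, B)`; runs closer than 100 ms are merged, since two
distinct equine complexes cannot be that close. The threshold is global per
record; an optional sliding-block mode (`block_s`) exists for drifting
records but is off by default.

Energies, LM/Lm and the threshold all scale with the square of the signal
amplitude, so the detected intervals are exactly invariant under positive
rescaling of the ECG. On 60 s synthetic records at 20 dB SNR the detector
achieves sensitivity and precision ≥ 0.95 with ±75 ms matching, and the
median onset-marker error stays below 40 ms (frame quantization is 16 ms;
the energy rise is dominated by the R upstroke, so A sits between the true Q
onset and the R peak).

## Motion detection

The acceleration module is mean-subtracted (removing gravity, hence offset
invariance) and rectified, and the robust threshold

    T = median(p) + 1.4826 · MAD(p)

is computed on the resulting series `p`. Two practical refinements are
applied, both configurable:

- `p` is smoothed with a 0.5 s moving average before thresholding. Rectify
  + low-pass is the classic envelope detector; without it a burst fragments
  at every zero crossing of its oscillation.
- Raw above-threshold runs shorter than 0.2 s are discarded. For any
  continuous noise distribution the robust threshold sits roughly 1.3 robust
  SDs above the quiet median, so isolated noise samples cross it constantly
  (measured ~20% of quiet samples); they are single-sample blips and are
  removed before dilation, otherwise the subsequent padding would mark the
  whole record as motion.

Surviving runs are dilated by `pad_s = 0.5` s on each side (the electrode
disturbance outlasts the mechanical burst) and merged. Median, MAD and the
samples all scale together, so detection is exactly scale- and
offset-invariant. Against the generator's dilated burst windows the detected
mask reaches a Jaccard overlap ≥ 0.8 on every tested seed (typically ~0.9;
the loss is concentrated at the tapered burst edges).

## Stationary wavelet transform

The decomposition is the à trous (undecimated) scheme with the orthonormal
Haar pair, 5 levels: at level `j` the filters are upsampled by inserting
`2^(j−1) − 1` zeros between taps and applied by circular convolution with no
decimation, so every level retains the signal length and the transform is
exactly shift-invariant. The input is padded to the next multiple of `2^5`
by edge replication and trimmed after reconstruction. Filters are
√2-normalized at every level; the fixed indexing convention is

    A_j[k] = Σ_l h[l] · A_{j−1}[(k + 2^(j−1) l) mod N]

and likewise with `g` for details. For any paraunitary pair the adjoint
identity `(H*H + G*G)/2 = I` holds, giving an exact inverse (round-trip
error < 1e−15 in practice; the test bound is 1e−9). Level 1 is the finest
scale. With Haar at 250 Hz the nominal detail bands are 62.5–125, 31–62.5,
15.6–31, 7.8–15.6 and 3.9–7.8 Hz, with the approximation below 3.9 Hz —
nominal because the two-tap Haar response rolls off slowly, so adjacent
levels leak into each other substantially (a 40 Hz tone puts only ~80% of
its detail energy into levels 1–3 even though level 2 dominates). Other
orthonormal wavelets can be selected by name (resolved through PyWavelets);
Haar is the default for its exact, edge-effect-free invertibility.

## Artifact estimation and removal

Inside the wavelet domain, per level:

1. **Gating.** The three finest detail levels are zeroed outside motion
   segments: there, fine-scale content is cardiac by assumption and must not
   enter the artifact.
2. **Bounds.** For every detail level and the approximation, maxima and
   minima of the coefficients are collected over non-overlapping 1 s frames
   (trailing partial frame dropped), and robust statistics of the two
   distributions give `M_j = median(max) + 1.4826·MAD(max)` and
   `m_j = median(min) − 1.4826·MAD(min)`. The bounds are meant to describe
   the artifact-free cardiac range, so frames overlapping motion segments
   are excluded from these statistics (falling back to all frames when fewer
   than 10 clean frames exist). This matters: on records that move more than
   half the time the all-frames median is itself an artifact frame, the
   bounds inflate to artifact scale and removal collapses (measured: minimum
   per-subject relative reduction drops from ~60% to ~15% on the default
   suite). The all-frames variant remains available
   (`threshold_frames="all"`).
3. **Attribution.** Coefficients outside `[m_j, M_j]` *and* inside motion
   segments belong to the artifact. The default mode takes the whole
   out-of-band coefficient ("full"); the alternative "exceedance" mode takes
   only `c − M_j` / `c − m_j`. Exceedance preserves in-band cardiac content
   but leaves the clipped remnant of large slow wander — a residual with
   amplitude of order the band edge — which measurement shows is enough to
   keep most corrupted windows above the artifact criterion; full mode
   sacrifices the (small) in-band cardiac share inside bursts and removes
   the artifact body, and is therefore the default.
4. **QRS protection.** At the three finest levels, samples inside detected
   QRS complexes are excluded from the artifact, so the ventricular
   deflection — the only clean fine-scale content inside a burst — is not
   subtracted. Coarser levels need no protection because their bounds are
   derived from frames that almost always contain a QRS, placing normal QRS
   coefficients inside the band.
5. **Reconstruction and subtraction.** The artifact coefficient set is
   inverted with the exact ISWT and the waveform is gated to the motion
   support (zero outside), then subtracted from the band-passed ECG.
   Wherever the artifact estimate is zero the cleaned output is bit-identical
   to the band-passed input.

The whole pipeline is scale-equivariant: scaling the ECG by `c > 0` scales
thresholds, artifact estimate and cleaned output by `c`.

## NLMS comparator

Adaptive noise cancellation with primary input `x = s + n₀` (band-passed
ECG) and reference `n₁` (mean-subtracted acceleration module): an FIR filter
of `L = 32` taps driven by the reference is adapted per sample with the
power-normalized update `w ← w + μ/(ε + ‖u‖²)·z·u`, zero-initialized,
minimizing the output power `E[z²]` and hence `E[(n₀ − y)²]`. The reference
choice is a design decision — the module is the only artifact-correlated
exogenous signal in the system. Because that reference is intermittent
(near-silent between bursts), the wrapper uses `μ = 0.1` and a regularizer
scaled to the reference power, `ε = 0.1·L·mean(n₁²)`; with a tiny absolute
`ε` the normalized step diverges on quiet segments and the filter chases the
ECG itself (measured: the cleaned record gets *worse* than raw). The filter
can only cancel the component of the artifact that is linearly predictable
from the reference, so its reduction is positive but far below the wavelet
pipeline's (~10% vs ~65–70% mean relative reduction on the default suite) —
comparisons should be read as an ordering, not exact percentages.

## Synthetic data

The generator emulates the target recordings and provides exact ground truth.

- **ECG**: sum of Gaussian bumps per beat (P, Q, R, S, T), default amplitudes
  0.2/−0.15/2.0/−0.4/0.45 mV at offsets −350/−30/0/+38/+450 ms with widths
  40/8/14/12/60 ms — a large monophasic R with prominent T, loosely following
  the equine base-apex lead, total QRS duration ~130 ms. Beat times follow
  RR = 1.5 s (configurable down to ~1.1 s across subjects) with 5% fractional
  jitter. Ground-truth QRS intervals span Q onset (3σ before the Q center) to
  S offset. Optional white noise at a stated SNR (35 dB in the study suite).
- **Accelerometer**: per-axis gravity share plus 0.01 g micro-noise; inside
  each burst a smooth (< 4 Hz) random oscillation of peak amplitude
  ~0.6–1.0 g, split across axes by a random direction and tapered at the
  edges. Bursts are placed uniformly at random, non-overlapping, ≥ 1.5 s
  apart.
- **Artifacts**, supported only on burst windows dilated by 0.5 s and tapered
  to zero at window edges, with amplitudes driven by the smoothed rectified
  deviation of the module from its resting level `e(t)`:
  wander — 0.5–3 Hz oscillation taken from the accelerometer's own band-passed
  low-frequency content, amplitude `5.0·e` mV; step — smoothed offset rising
  inside the burst and persisting to the window end, amplitude
  `3.5·mean(e)` mV; spike — Poisson-placed 15–40 ms transients at
  high-acceleration moments, amplitude `6.0·(e + 0.3)` mV. Deriving the
  wander from the accelerometer makes part of the artifact linearly
  predictable from the reference, which is what gives the NLMS comparator a
  fair footing. The gains are calibrated so the in-burst artifact RMS is at
  least 3× the clean-ECG RMS (measured 3.9–4.8× across seeds): corrupted
  stretches are visually dominated by the artifact.
- **Study suite** (`make_study`): 7 subjects × 600 s by default, per-subject
  parameters drawn uniformly (RR 1.1–1.5 s, amplitude scale 0.85–1.15, burst
  coverage 0.53–0.66, burst length 4–8 s, burst amplitude 0.6–1.0 g, overall
  artifact gain 0.9–1.3), seeds derived deterministically from one master
  seed. Coverage is calibrated so the raw MA-affected percentage falls in the
  40–75% band that characterizes heavily corrupted ambulatory recordings.

What the generator does **not** emulate: arrhythmias and AV blocks (common in
horses), T-wave morphology variability, respiration, electrode pop/saturation,
or artifacts outside motion bursts. Passing tests therefore show that the
pipeline removes *motion-correlated* artifacts of realistic magnitude on a
stylized cardiac background; they do not certify performance on pathological
rhythms or on artifacts with no accelerometer signature.

## Evaluation

A 1 s window is MA-affected when the RMS of the residual artifact in it
exceeds `beta = 1` times the overall RMS of the clean reference. Raw and
cleaned signals are scored against the *band-passed* clean truth (raw
residual = band-passed observed − band-passed clean), so the band-pass itself
is not counted as error. Reported per subject: raw and cleaned percentages,
their difference, and the relative reduction `100·(raw − cleaned)/raw`. This
windowed-RMS criterion replaces expert visual labelling — the only
automatable, seed-reproducible stand-in — and is stricter than visual
inspection for low-grade residuals. Bland–Altman statistics (bias, SD of
differences, limits of agreement at ±1.96 SD, trend slope of differences
against means) are provided for comparing marker time series.
`scripts/acceptance.py` reports the minimum per-subject relative reduction of
the default suite; at the default conditions it computes ≈ 54% (seed 42),
clearing the 40% mark on every subject.

## Numerical choices and degenerate inputs

- Intervals are half-open, 0-based sample indices; construction sorts and
  merges overlaps, making set algebra (masks, complement, dilation) exact.
- CSV I/O writes floats with `%.17g` and parses with round-trip precision, so
  save/load is bit-exact.
- Empty inputs (signals, value series, interval sets) raise `ValueError`
  rather than returning degenerate results; an empty *detection* result is
  valid and yields an identity cleaning pass.
- `frame_energy` requires at least one full window; threshold estimation
  requires at least one full 1.5 s interval; `frame_extrema` at least one
  full frame. Trailing partial frames are dropped everywhere.
- The no-jitter beat grid is generated from an analytic cumulative sum and
  half-up rounding so R spacing is exactly `RR·fs` samples.

## Problem sizes

Default test and acceptance runs use 60–600 s records; the full acceptance
computation (7 × 600 s subjects, both methods) completes in well under a
minute on one CPU, and the whole test-suite in under half a minute. Longer
records only improve the robust statistics (more clean frames per record).
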