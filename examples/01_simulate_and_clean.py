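"""Generate one corrupted recording, clean it, and quantify the improvement.

Builds a 5-minute synthetic subject (equine-like ECG at 250 Hz, triaxial
accelerometer at 25 Hz, motion-correlated artifacts), runs the full
wavelet-based removal pipeline, and reports the RMS error against the clean
ground truth plus the artifact-affected percentage before and after.
"""

import numpy as np

from swmar import (bandpass_ecg, generate_truth, ma_fraction, remove_artifacts)

truth = generate_truth(duration_s=300, seed=1)
rec = truth.recording
fs = rec.fs_ecg

result = remove_artifacts(rec)
clean_bp = bandpass_ecg(truth.clean_ecg, fs)
observed_bp = bandpass_ecg(rec.ecg, fs)

rmse_before = np.sqrt(np.mean((observed_bp - clean_bp) ** 2))
rmse_after = np.sqrt(np.mean((result.cleaned - clean_bp) ** 2))
pct_before = ma_fraction(observed_bp - clean_bp, clean_bp, fs)
pct_after = ma_fraction(result.cleaned - clean_bp, clean_bp, fs)

print(f"motion segments detected : {len(result.motion)}")
print(f"QRS complexes detected   : {len(result.qrs)}")
print(f"RMSE vs clean truth (mV) : {rmse_before:.3f} -> {rmse_after:.3f}")
print(f"MA-affected windows (%)  : {pct_before:.1f} -> {pct_after:.1f}")
print(f"relative reduction (%)   : {100 * (pct_before - pct_after) / pct_before:.1f}")
# RMSE drops because the reconstructed artifact waveform is subtracted only
# inside motion segments; the affected percentage counts 1 s windows whose
# residual RMS still exceeds the clean record's overall RMS.
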