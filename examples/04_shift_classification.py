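"""Secondary structure from Ca/Cb chemical shifts, and peak back-prediction.

A threonine with Ca ~61.2 ppm and Cb ~72.3 ppm carries the beta-sheet
signature (Cb shifted to high frequency, Ca to low).  Assignment tables
expand into the peak lists expected in NCA/NCO correlation spectra.
"""

import pandas as pd

from maturation.shifts import (
    ShiftObservation,
    class_posterior,
    classify_cb_band,
    load_shift_statistics,
    predict_correlation_peaks,
)

stats = load_shift_statistics()
obs = ShiftObservation("THR", ca=61.2, cb=72.3)
post = class_posterior(obs, stats)
print("Thr Ca 61.2 / Cb 72.3 ppm posterior:")
for cls, p in sorted(post.probabilities.items(), key=lambda kv: -kv[1]):
    print(f"  {cls:5s} {p:.3f}")
cls, z, _ = classify_cb_band(72.3, "THR", stats)
print(f"Cb-band call: {cls} (z-scores: " +
      ", ".join(f"{c}={v:.2f}" for c, v in z.items()) + ")")

table = pd.DataFrame(
    [(1, "GLY", "N", 108.0), (1, "GLY", "CA", 45.2), (1, "GLY", "C", 172.0),
     (2, "THR", "N", 115.0), (2, "THR", "CA", 61.5), (2, "THR", "C", 173.5),
     (3, "SER", "N", 116.5), (3, "SER", "CA", 57.8), (3, "SER", "C", 172.8)],
    columns=["residue_index", "residue_type", "atom_name", "shift"],
)
for exp in ("NCA", "NCO"):
    peaks = predict_correlation_peaks(table, exp)
    print(f"{exp}: {len(peaks)} peaks (3 residues; NCO skips the first, "
          "which has no preceding carbonyl)" if exp == "NCO"
          else f"{exp}: {len(peaks)} peaks")
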