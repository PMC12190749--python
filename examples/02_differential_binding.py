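"""Negative-binomial differential binding with planted fold changes.

Simulates a 3 vs 3 count matrix where 20% of peaks carry a 4-fold change
(dispersion 0.1), then tests every peak with the NB likelihood-ratio
test and BH-adjusts.  Sensitivity is the fraction of planted peaks
recovered at FDR < 1%.
"""

import numpy as np

from markdyn.diffbind import differential_binding
from markdyn.simulate import simulate_count_benchmark

counts, is_db = simulate_count_benchmark(
    n_peaks=2000, n_per_group=3, phi=0.1, fold_change=4.0, db_fraction=0.2, seed=7
)
result = differential_binding(counts, "A", "B")

called = result.fdr < 0.01
sensitivity = float(called[is_db].mean())
fdp = float((~is_db[called.values]).mean()) if called.any() else 0.0
print(f"{int(is_db.sum())} planted 4-fold peaks among {len(result)}")
print(f"called at FDR<1%: {int(called.sum())}  sensitivity={sensitivity:.3f}  "
      f"false discovery proportion={fdp:.3f}")
print(f"median |log2FC| of planted peaks: "
      f"{np.median(np.abs(result.log2_fold_change[is_db])):.2f} (truth: 2.0)")
# A sensitivity near 1 with FDP around or below 0.01 shows the test is both
# powerful and calibrated at this depth and replication.
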