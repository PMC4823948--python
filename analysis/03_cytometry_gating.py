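#!/usr/bin/env python
"""PI-gating and surface-CALR positivity on simulated event tables.

Sweeps the true marker-positive weight from 0 to 0.9, gates each table on
an automatically calibrated PI threshold, scores the positive fraction
among live events with its Clopper-Pearson 95% CI, and reports the mean
absolute estimation error. Writes results/cytometry/recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import icd_profiler as icd

OUT = Path("results/cytometry")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 11

model = icd.ThresholdModel(
    assay="CALR_surface", direction="above", neg_mean=0.0, neg_sd=1.0,
    threshold=icd.EventSpec().true_marker_boundary(), method="fixed",
)

rng = np.random.default_rng(SEED)
rows = []
for p in np.arange(0.0, 0.91, 0.1):
    for rep in range(20):
        spec = icd.EventSpec(
            n_events=10_000, marker_positive_fraction=float(p),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        events, truth = icd.generate_events(spec)
        pi_thr = icd.auto_pi_threshold(events)
        live, live_frac = icd.gate_live(events, pi_thr)
        res = icd.marker_positive_fraction(live, model)
        rows.append(
            dict(true_fraction=float(p), rep=rep, pi_threshold=pi_thr,
                 live_fraction=live_frac, estimate=res.fraction,
                 ci_low=res.ci_low, ci_high=res.ci_high,
                 abs_error=abs(res.fraction - p))
        )

table = pd.DataFrame(rows)
table.to_csv(OUT / "recovery.csv", index=False)
by_p = table.groupby("true_fraction")["abs_error"].mean()
print("Mean |estimate - truth| by true positive fraction:")
print(by_p.to_string(float_format=lambda x: f"{x:.4f}"))
print(f"\nOverall MAE: {table.abs_error.mean():.4f} "
      f"(live gate retains {table.live_fraction.mean():.3f} on average; "
      f"generator live fraction 0.7)")
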