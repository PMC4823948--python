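# icd-profiler

Quantification pipeline for the hallmarks of **immunogenic cell death
(ICD)** in high-content screening data, with a fully ground-truthed
synthetic-data generator for validation.

ICD is operationally defined by a set of biosensor readouts in treated
cell cultures and tissue:

| Hallmark | Readout | Direction of the positive call |
|---|---|---|
| Calreticulin (CALR) exposure | CALR-GFP cytoplasmic aggregation → granularity score | above threshold |
| ATP release | quinacrine-stained vesicle depletion → granularity score | below threshold |
| HMGB1 exodus | nuclear HMGB1-GFP mean intensity | below threshold |
| Type-1 interferon response | whole-cell MX1-promoter-GFP mean intensity | above threshold |
| Surface CALR (cytometry) | AF488 marker among PI⁻ (viable) events | above threshold |
| Tissue necrosis | eosin/hematoxylin ratio and low-hematoxylin area fraction | — |

The package covers the whole chain: seeded simulation of microscopy
fields, event tables and HE tissue; nuclear segmentation with debris
exclusion and cytoplasmic ring ROIs; per-cell features; control-based
threshold calibration; well-level summaries and dose–response statistics;
PI-gated cytometry; and HE stain separation.

## The statistics at the core

**Granularity score.** For a cytoplasmic ROI the image is tiled into
non-overlapping `b × b` pixel blocks (default `b = 4`, anchored at the ROI
bounding box). With block mean intensities `m₁ … m_k` (blocks ≥ 50% inside
the ROI) and ROI mean `μ`,

```
G = sd(m₁ … m_k) / μ        (sample SD, n − 1 denominator)
```

`G` is dimensionless, zero for a uniform ROI, exactly invariant to
intensity scaling, and increases with the aggregation of the biosensor
into puncta.

**Control-calibrated thresholds.** Gaussians `N(μ₋, σ₋)` and `N(μ₊, σ₊)`
are fitted to the negative and positive control populations of each
assay; the decision threshold is their equal-likelihood intersection
(the root of `log φ₋(x) = log φ₊(x)` between the means; the midpoint for
equal SDs). Without a positive control the rule falls back to
`μ₋ ± k·σ₋` (default `k = 3`).

**Group statistics.** Conditions are compared to untreated controls with
the two-tailed Welch t-test (Satterthwaite degrees of freedom), starred
`*`, `**`, `***` for `p < 0.05, 0.01, 0.001`. Positive fractions of event
tables carry Clopper–Pearson exact 95% CIs.

## Worked example

The granularity statistic on a hand-checkable ROI — two full 4×4 blocks
with uniform values 10 and 30, so `sd = √200 ≈ 14.14`, `μ = 20`:

```python
>>> import numpy as np
>>> from icd_profiler import granularity_score
>>> img = np.zeros((4, 8)); img[:, :4] = 10; img[:, 4:] = 30
>>> granularity_score(img, np.ones((4, 8), bool), block_px=4)
0.7071067811865476
```

A synthetic HE tissue with a known 25% necrotic disc and 40 planted
leukocytes, quantified by the tissue pipeline:

```bash
$ icd-profiler simulate tissue --seed 5 --out demo
wrote tissue.png (necrotic fraction 0.250, 40 leukocytes)
$ icd-profiler histo --in demo/tissue.png --out demo
{
 "mean_eosin_hematoxylin_ratio": 1.4779159738821293,
 "low_hematoxylin_area_fraction": 0.24927902221679688,
 "hematoxylin_threshold": 0.29557798668905916,
 "leukocytes_per_field": 40
}
```

The low-hematoxylin fraction recovers the planted 0.25 and the leukocyte
count is exact.

A full simulated 24-well plate run (`icd-profiler run --assay MX1_GFP
--seed 11 --out results/mx1`, or `python analysis/02_imaging_plates.py`
for all four assays) calibrates the threshold on control wells and prints
a dose–response table such as:

```
treatment  dose      role  n_wells    mean       sd      t     df         p  stars
     drug     1   treated        3 0.05402  0.01078  5.066  3.185   0.01283      *
     drug     3   treated        3  0.1603 0.007773  24.89  3.805 2.354e-05    ***
     drug    10   treated        3  0.4823  0.03714  21.38   2.11  0.001674     **
     drug    30   treated        3  0.7956  0.01172  101.7  3.031   1.87e-06   ***
     drug   100   treated        3   0.916 0.007543  159.6   3.85 1.687e-08    ***
```

i.e. the fraction of MX1-GFP-positive cells per well rises along the
generated logistic dose–response, and each dose is compared to the
untreated wells by Welch's test.

## Repository layout

- `src/icd_profiler/` — the library: `synthetic` (generators + ground
  truth), `segmentation`, `features`, `calibration`, `cytometry`,
  `histology`, `pipeline`, `cli`.
- `analysis/01…04_*.py` — numbered narrative drivers that run each stage
  on simulated data and write tables under `results/`.
- `tests/` — unit, property and end-to-end validation tests.

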