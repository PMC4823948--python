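# Methods

This note documents the models, parameter choices and numerical
conventions behind `icd_profiler`, and what the synthetic-data validation
does and does not establish about real data.

## Synthetic microscopy fields

A view field is rendered as three 16-bit channels (Hoechst, biosensor
"GFP", PI) of additive signals plus noise:

* **Nuclei** are rotated ellipses with radii `N(7, 0.8)` px (clipped at
  3 px), placed by per-cell rejection sampling (up to 10⁴ attempts, then
  an explicit placement error) with a minimum center gap of
  `r_i + r_j + 14` px. The gap guarantees that no cell's rendered
  biosensor signal can reach a neighbour's measured ROI, so every
  per-cell label is unambiguous. Each field defaults to 80 cells on a
  400×400 px raster (within the realistic 50–300 cells/field range of a
  20× high-content acquisition; the source protocol does not state a
  density, so this is a package choice).
* **Dead (PI⁺) cells** (default 5%) get a condensed nucleus (radii ×0.7),
  1.8× brighter Hoechst and a strong PI signal (3000 counts over a
  30-count background), so viability gating and debris handling are
  genuinely exercised.
* **Biosensors.** The diffuse compartment is rendered over the whole cell
  footprint — nucleus, the 5-px cytoplasmic ring matching the measured
  ROI, and a 3-px outer margin — reflecting that a widefield projection
  of the ER/vesicle compartment overlaps the nucleus and extends slightly
  beyond any ring ROI. This makes features robust to ±1–2 px
  segmentation-boundary error instead of encoding the ROI into the image.
  - *CALR-GFP / quinacrine:* diffuse level 100 counts; "granular" cells
    additionally receive 12 Gaussian puncta (σ = 1.5 px, amplitude 40)
    placed uniformly in the cytoplasmic annulus, and the cell's total
    intensity is renormalized so diffuse and granular cells have the same
    mean — the granularity score must react to texture, not brightness.
    For CALR the treated (responder) phenotype is granular; for
    quinacrine the responder has *lost* its vesicles (diffuse).
  - *HMGB1-GFP:* nuclear level 300 counts over background, dropping to
    0.2× on release; cytoplasm at 30.
  - *MX1-GFP:* whole-cell 30 counts, ×10 on induction.
* **Noise:** Poisson shot noise on the expected counts plus Gaussian read
  noise (σ = 3), mimicking an sCMOS camera qualitatively. With these
  levels the granularity noise floor is ≈ 0.033 and the 12-granule
  responder mode ≈ 0.13, a ~5σ separation; granule counts
  {0, 5, 15, 40} map to strictly increasing mean scores. Amplitude and
  count were chosen so the score is still rising at 40 granules (beyond
  ~70 granules the puncta merge and the score would saturate).

Every generator draws from a single `numpy` Generator seeded by one
integer, so all outputs are bit-reproducible.

### Plates

`generate_plate` assigns each well a latent responder fraction: the
logistic dose–response `floor + (ceil−floor)/(1+(EC50/dose)^h)` (defaults
floor 0.02, ceiling 0.95, EC50 10, Hill 1.5) for treated wells, the floor
for negative controls, and 0.98 for positive controls. The default layout
is a 24-well plate (3 neg + 3 pos controls, 6 doses × 3 replicate wells)
with six view fields per well, matching the acquisition design the
pipeline targets. Cells' responder flags are i.i.d. Bernoulli draws of
the latent fraction; the per-well *realized* fraction among live cells is
recorded as the recovery target, so recovery tests measure classification
accuracy rather than re-testing binomial sampling noise.

### Event tables and tissue

Cytometry events are two log-normal PI components (live: ln 50 ± 0.4;
dead: ln 2000 ± 0.4, 30% dead) with a log-normal marker mixture among
live events (negative ln 100 ± 0.35, positive ln 1000 ± 0.35). The
generator exposes the analytic equal-likelihood boundaries of both
mixtures for validation.

HE tissue is composed by Beer–Lambert absorption,
`I = 256·10^(−D·S) − 1` on the standard hematoxylin/eosin OD basis
(rows of `S`: [0.650, 0.704, 0.286] and [0.072, 0.990, 0.105],
normalized). Density maps are piecewise constant (hematoxylin 0.7 / eosin
0.4 in viable tissue, 0.12 / 0.8 in the necrotic disc) plus smoothed
Gaussian noise (σ = 0.05 OD); stain levels are kept moderate so that
8-bit quantization leaves the deconvolution round trip conservative to
<1% relative RMS. Leukocytes are hard discs of radius 2.5 px adding 1.3
OD of hematoxylin, planted with ≥10 px separation.

## Measurement pipeline

* **Segmentation:** 3×3 median filter, Otsu threshold, hole filling,
  distance-transform watershed (peaks on a σ=1-smoothed EDT,
  `min_distance` 7 px) to split touching nuclei; border-touching objects
  are excluded by default (their cytoplasm would be truncated). A
  bimodality guard (foreground–background contrast must exceed 2× the
  image SD) returns an empty mask on background-only images instead of
  labelling noise. The thresholding method is a package choice — the
  commercial software used for such screens does not publish its
  internals.
* **Debris filter:** objects outside [25, 5000] px² or below a Hoechst
  intensity floor are dropped. 25 px² sits above the largest rendered
  debris speck (~13 px²) and below the smallest condensed dead nucleus;
  the cut-offs are calibrated on the generator, not on published values.
* **Cytoplasmic ROIs:** each nucleus is expanded by a 5-px ring
  (`skimage.segmentation.expand_labels`), contested pixels going to the
  nearest nucleus; nucleus and cytoplasm are disjoint and rings of
  different cells never overlap.
* **Granularity:** blocks are anchored at the ROI bounding-box origin;
  blocks with <50% ROI coverage are discarded rather than partially
  weighted (edge blocks would otherwise inflate the SD). Sample (n−1) SD.
  Cells with <2 valid blocks or zero ROI mean get a NaN sentinel and a QC
  log entry. The biosensor channel has the per-image median subtracted
  (floored at 0) before measurement by default; the median estimates the
  background plateau since cells cover a minority of the field. Raw-mode
  is available via `background_subtract=False`.
* **Viability:** a cell is live when its nuclear PI mean is below 500
  counts, which sits far from both generated modes (~30 vs ~3000).

## Calibration and statistics

Thresholds are the equal-likelihood intersection of the control
Gaussians, computed in closed form (quadratic in `x`; the root between
the means is taken, the midpoint for equal SDs). Degenerate controls
(zero variance, equal means, inverted direction) raise errors; a missing
positive control triggers the documented `k·σ` fallback (k = 3) with a
warning. Assay directions: CALR and MX1 positive above, quinacrine and
HMGB1 positive below.

Wells are summarized over live cells only; wells with fewer than 50
viable cells are flagged "insufficient viable cells" and excluded from
group statistics — mirroring the practical caveat that near-complete
killing leaves too few PI-negative cells to score. Dose–response tables
report per-condition mean ± SD over replicate wells and a Welch t-test
against the untreated wells with `*/**/***` stars; no multiple-testing
correction is applied across doses by default (per-comparison stars, as
is conventional for such figures), with an optional Holm flag.

The PI gate threshold for event tables is fitted on log intensities
(Otsu split, then per-side Gaussian fits, then the intersection), since
cytometry intensities are close to log-normal. Positive fractions carry
Clopper–Pearson exact 95% CIs (`statsmodels`).

## Tissue quantification

Optical density is `−log10((I+1)/256)` per channel; densities are the
least-squares projection onto the stain basis, clipped at 0 (collinear
bases are rejected). The low-hematoxylin (necrotic) area fraction
thresholds the hematoxylin histogram within the tissue mask (total OD >
0.15) by Otsu, with two guards: the top percentile of values is excluded
from the threshold estimate so sparse dense puncta (leukocytes, condensed
nuclei) cannot pose as the "high" mode, and if the two Otsu classes are
closer than 0.3 OD the histogram is treated as unimodal and the fraction
is ≈ 0. Leukocytes are counted as connected components more than 0.35 OD
above the region's median hematoxylin density, size-banded to 2–8 px
equivalent diameter; working in OD space relative to the median makes the
count invariant to uniform brightness changes (verified at ±20%).

## Problem sizes used in validation

Validation runs use 24-well plates × 6 fields × 80 cells/field per assay,
50 seeded fields for count recovery, 10⁴-event tables (20 replicates ×
10 true fractions), 10⁴ null simulations for the Welch type-I error, and
512² tissue images — sizes chosen so the whole suite runs in minutes on a
single CPU while every binomial CI is narrow enough to be informative.

## What passing tests do and do not show

The generator realizes each phenotype exactly as labelled, with
non-overlapping cells, flat backgrounds, stationary noise and known stain
vectors. Recovery therefore demonstrates the *internal correctness* of
the operators (the granularity statistic matches its definition;
calibration finds the Bayes boundary; the area fraction equals the
planted one) — not robustness to confluent cultures, uneven illumination,
focus drift, autofluorescence, stain variability between labs, or
segmentation of clumped tissue nuclei. No point-spread function, optics
or 3-D structure is modelled. The leukocyte counter is validated against
synthetic puncta only; whether the original tissue counts were manual or
automated is unknown.

## Known limitations

* Gaussian threshold calibration assumes roughly Gaussian feature
  distributions in the controls; strongly skewed features should be
  transformed first (the cytometry path does this with logs).
* `run_plate_analysis` operates on simulated plates; real images enter
  through the `segment`/`measure` CLI on multi-page TIFFs plus a layout
  CSV.
* FCS binary parsing, spectral compensation, EC50 curve fitting and
  plate-effect normalization are out of scope.
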