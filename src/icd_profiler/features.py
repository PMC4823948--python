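"""Per-cell measurement operators.

The central statistic is the granularity score of a cytoplasmic ROI: the
sample standard deviation of the mean intensities of non-overlapping
square blocks of adjacent pixels, divided by the mean intensity of the
whole ROI. Aggregated (vesicular) biosensor distributions score high,
diffuse ones near zero, and the ratio construction makes the score exactly
invariant to uniform intensity scaling.

Also provided: nuclear mean intensity (HMGB1-GFP retention), whole-cell
mean intensity (MX1-GFP induction), and the per-field driver that fills a
CellRecord per segmented cell with the assay-appropriate feature, the PI
readout and the live/dead call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .calibration import ASSAY_FEATURES
from .segmentation import CellROIs
from .synthetic import FieldImage

#: sentinel for a feature that could not be computed for a cell
UNDEFINED = float("nan")

RECORD_COLUMNS = [
    "cell_id",
    "well",
    "field",
    "assay",
    "nucleus_area_px",
    "nucleus_mean_hoechst",
    "granularity_score",
    "nuclear_biosensor_mean",
    "cell_mean_gfp",
    "pi_mean",
    "live",
]


def granularity_score(
    channel: np.ndarray,
    roi: np.ndarray,
    block_px: int = 4,
    min_coverage: float = 0.5,
) -> float:
    """SD of block mean intensities over the ROI mean intensity.

    Blocks form a non-overlapping ``block_px`` x ``block_px`` grid anchored
    at the ROI bounding-box origin; a block enters the statistic when at
    least ``min_coverage`` of its pixels lie inside the ROI, and its mean
    is taken over those ROI pixels only. The SD uses the n-1 denominator.
    Returns NaN (undefined) when fewer than two valid blocks exist or the
    ROI mean is zero.
    """
    roi = np.asarray(roi, dtype=bool)
    img = np.asarray(channel, dtype=float)
    if img.shape != roi.shape:
        raise ValueError("channel and ROI shapes differ")
    if block_px < 2:
        raise ValueError("block_px must be >= 2")
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must be in (0, 1]")
    if not roi.any():
        raise ValueError("ROI is empty")

    ys, xs = np.nonzero(roi)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = img[y0:y1, x0:x1]
    m = roi[y0:y1, x0:x1]
    b = block_px
    ph = (-sub.shape[0]) % b
    pw = (-sub.shape[1]) % b
    sub = np.pad(sub, ((0, ph), (0, pw)))
    m = np.pad(m, ((0, ph), (0, pw)))
    nby, nbx = sub.shape[0] // b, sub.shape[1] // b
    sums = (sub * m).reshape(nby, b, nbx, b).sum(axis=(1, 3))
    counts = m.reshape(nby, b, nbx, b).sum(axis=(1, 3))
    valid = counts >= min_coverage * b * b
    if valid.sum() < 2:
        return UNDEFINED
    roi_mean = img[roi].mean()
    if roi_mean <= 0:
        return UNDEFINED
    block_means = sums[valid] / counts[valid]
    return float(block_means.std(ddof=1) / roi_mean)


def nuclear_mean_intensity(channel: np.ndarray, nucleus: np.ndarray) -> float:
    """Arithmetic mean of the channel over the nucleus mask."""
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise ValueError("nucleus mask is empty")
    return float(np.asarray(channel, dtype=float)[nucleus].mean())


def cell_mean_intensity(
    channel: np.ndarray, nucleus: np.ndarray, cytoplasm: np.ndarray
) -> float:
    """Mean of the channel over the whole cell (nucleus union cytoplasm)."""
    union = np.asarray(nucleus, dtype=bool) | np.asarray(cytoplasm, dtype=bool)
    if not union.any():
        raise ValueError("nucleus union cytoplasm is empty")
    return float(np.asarray(channel, dtype=float)[union].mean())


def subtract_background(channel: np.ndarray) -> np.ndarray:
    """Subtract the per-image median (background estimate), floored at 0.

    Cells cover a minority of a view field, so the image median estimates
    the background plateau; subtracting it makes SD/mean features
    comparable across fields with different stray-light levels.
    """
    img = np.asarray(channel, dtype=float)
    return np.clip(img - np.median(img), 0.0, None)


def measure_field(
    field: FieldImage,
    rois: CellROIs,
    assay: str,
    pi_threshold: float = 500.0,
    block_px: int = 4,
    min_coverage: float = 0.5,
    background_subtract: bool = True,
    biosensor_channel: str = "gfp",
    pi_channel: str = "pi",
    hoechst_channel: str = "hoechst",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every segmented cell of one field.

    Populates the assay-appropriate feature (granularity for CALR_GFP and
    QUINACRINE, nuclear mean for HMGB1_GFP, whole-cell mean for MX1_GFP);
    the PI mean over the nucleus and the live flag (PI mean below
    ``pi_threshold``) are always populated. Returns ``(records, qc)``
    where ``qc`` lists cells whose feature was undefined and why.
    """
    if assay not in ASSAY_FEATURES:
        raise ValueError(f"unknown assay {assay!r}")
    feature_col = ASSAY_FEATURES[assay][0]

    sensor = np.asarray(field.channels[biosensor_channel], dtype=float)
    if background_subtract:
        sensor = subtract_background(sensor)
    pi_img = np.asarray(field.channels[pi_channel], dtype=float)
    hoechst = np.asarray(field.channels[hoechst_channel], dtype=float)

    nuc_slices = ndi.find_objects(rois.nucleus_labels)
    cyto_slices = ndi.find_objects(rois.cytoplasm_labels)

    rows = []
    qc_rows = []
    for cid in rois.cell_ids:
        cid = int(cid)
        ns = nuc_slices[cid - 1]
        nuc = rois.nucleus_labels[ns] == cid
        pi_mean = float(pi_img[ns][nuc].mean())
        rec = dict(
            cell_id=cid,
            well=field.well,
            field=field.field,
            assay=assay,
            nucleus_area_px=int(nuc.sum()),
            nucleus_mean_hoechst=float(hoechst[ns][nuc].mean()),
            granularity_score=UNDEFINED,
            nuclear_biosensor_mean=UNDEFINED,
            cell_mean_gfp=UNDEFINED,
            pi_mean=pi_mean,
            live=bool(pi_mean < pi_threshold),
        )
        cs = cyto_slices[cid - 1] if cid - 1 < len(cyto_slices) else None
        if feature_col == "granularity_score":
            if cs is None:
                qc_rows.append(dict(cell_id=cid, well=field.well, field=field.field,
                                    reason="no cytoplasm ROI"))
            else:
                score = granularity_score(
                    sensor[cs], rois.cytoplasm_labels[cs] == cid,
                    block_px=block_px, min_coverage=min_coverage,
                )
                rec["granularity_score"] = score
                if not np.isfinite(score):
                    qc_rows.append(dict(cell_id=cid, well=field.well,
                                        field=field.field,
                                        reason="undefined granularity"))
        elif feature_col == "nuclear_biosensor_mean":
            rec["nuclear_biosensor_mean"] = float(sensor[ns][nuc].mean())
        else:  # whole-cell mean
            total = float(sensor[ns][nuc].sum())
            area = int(nuc.sum())
            if cs is not None:
                cyto = rois.cytoplasm_labels[cs] == cid
                total += float(sensor[cs][cyto].sum())
                area += int(cyto.sum())
            rec["cell_mean_gfp"] = total / area
        rows.append(rec)

    records = (
        pd.DataFrame(rows, columns=RECORD_COLUMNS)
        if rows
        else pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})
    )
    qc = pd.DataFrame(qc_rows, columns=["cell_id", "well", "field", "reason"])
    return records, qc
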