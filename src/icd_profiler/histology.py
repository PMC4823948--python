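"""HE tissue quantification.

Beer-Lambert color deconvolution separates an RGB HE image into
hematoxylin and eosin optical-density maps; from those the pipeline
derives the per-pixel eosin/hematoxylin ratio, the fraction of tissue with
low hematoxylin staining (the necrosis readout), counts of small
hematoxylin-dense puncta (infiltrating leukocytes) per view field, and the
percentage of marker-positive cells in immunofluorescence sections.

Optical density is ``-log10((I + 1) / 256)`` per channel; densities are
the least-squares projection of the OD vector onto the stain basis,
clipped at zero. The forward composition used by the synthetic generator
is the exact adjoint of this transform, so round trips are conservative up
to 8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import features as _features
from . import segmentation as _segmentation
from .synthetic import FieldImage


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: standard hematoxylin / eosin optical-density unit vectors (RGB order)
HEMATOXYLIN_OD = _unit([0.650, 0.704, 0.286])
EOSIN_OD = _unit([0.072, 0.990, 0.105])
HE_STAIN_MATRIX = np.stack([HEMATOXYLIN_OD, EOSIN_OD])  # rows = stains

I0 = 256.0


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit (or [0,1] float) RGB image."""
    img = np.asarray(rgb, dtype=float)
    if img.max() <= 1.0 and img.dtype.kind == "f":
        img = img * 255.0
    return -np.log10((img + 1.0) / I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, quantized to uint8."""
    intensity = I0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


@dataclass
class StainMaps:
    """Per-stain optical-density rasters and the basis used to obtain them."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    stain_matrix: np.ndarray


def deconvolve_he(
    rgb: np.ndarray, stain_vectors: Optional[np.ndarray] = None
) -> StainMaps:
    """Separate an RGB HE image into hematoxylin and eosin density maps."""
    S = HE_STAIN_MATRIX if stain_vectors is None else np.asarray(stain_vectors, float)
    if S.ndim != 2 or S.shape[1] != 3 or S.shape[0] < 2:
        raise ValueError("stain_vectors must be a (n_stains >= 2, 3) matrix")
    S = S / np.linalg.norm(S, axis=1, keepdims=True)
    if np.linalg.matrix_rank(S, tol=1e-6) < S.shape[0]:
        raise ValueError("stain vectors are collinear")
    od = rgb_to_od(rgb)
    pinv = np.linalg.pinv(S)  # (3, n_stains)
    density = np.clip(od @ pinv, 0.0, None)
    return StainMaps(
        hematoxylin=density[..., 0], eosin=density[..., 1], stain_matrix=S
    )


def recompose_he(
    hematoxylin: np.ndarray,
    eosin: np.ndarray,
    stain_matrix: np.ndarray = HE_STAIN_MATRIX,
) -> np.ndarray:
    """Beer-Lambert forward composition of density maps into RGB uint8."""
    od = (
        hematoxylin[..., None] * stain_matrix[0]
        + eosin[..., None] * stain_matrix[1]
    )
    return od_to_rgb(od)


def tissue_mask(maps: StainMaps, od_floor: float = 0.15) -> np.ndarray:
    """Pixels with appreciable total stain (excludes glass/background)."""
    return (maps.hematoxylin + maps.eosin) > od_floor


@dataclass
class NecrosisResult:
    """Eosin/hematoxylin ratio map and the low-hematoxylin area readout."""

    ratio_map: np.ndarray
    valid_mask: np.ndarray
    mean_ratio: float
    fully_masked: bool
    hematoxylin_floor: float
    low_hematoxylin_fraction: Optional[float] = None
    threshold: Optional[float] = None


def eosin_hematoxylin_ratio(
    maps: StainMaps,
    hematoxylin_floor: float = 0.1,
    mask: Optional[np.ndarray] = None,
) -> NecrosisResult:
    """Per-pixel eosin/hematoxylin ratio where hematoxylin is above a floor.

    Pixels below the floor (and outside the tissue mask, if given) are
    masked; the summary is the mean ratio over valid pixels, undefined
    when everything is masked.
    """
    if hematoxylin_floor <= 0:
        raise ValueError("hematoxylin_floor must be > 0")
    valid = maps.hematoxylin >= hematoxylin_floor
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    ratio = np.full(maps.hematoxylin.shape, np.nan)
    ratio[valid] = maps.eosin[valid] / maps.hematoxylin[valid]
    fully_masked = not valid.any()
    mean_ratio = float("nan") if fully_masked else float(ratio[valid].mean())
    return NecrosisResult(
        ratio_map=ratio,
        valid_mask=valid,
        mean_ratio=mean_ratio,
        fully_masked=fully_masked,
        hematoxylin_floor=hematoxylin_floor,
    )


def low_hematoxylin_area_fraction(
    maps: StainMaps,
    mask: np.ndarray,
    threshold_method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    min_separation: float = 0.3,
) -> tuple[float, float]:
    """Fraction of tissue pixels with low hematoxylin density.

    ``otsu`` thresholds the hematoxylin histogram within the tissue mask;
    the top percentile is excluded from the threshold estimate so that
    sparse hematoxylin-dense puncta (condensed nuclei, infiltrating
    leukocytes) cannot masquerade as the "high" tissue mode. When the two
    Otsu classes are closer than ``min_separation`` OD units the histogram
    is considered unimodal (no necrotic mode) and the fraction is measured
    below ``mean - 3*SD``, i.e. essentially zero. Returns
    ``(fraction, threshold)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    values = maps.hematoxylin[mask]
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for threshold_method='fixed'")
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        core = values[values <= np.quantile(values, 0.99)]
        thr = float(threshold_otsu(core))
        below, above = core[core < thr], core[core >= thr]
        if (
            len(below) == 0
            or len(above) == 0
            or above.mean() - below.mean() < min_separation
        ):
            thr = float(core.mean() - 3.0 * core.std())
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    return float((values < thr).mean()), thr


def count_leukocytes(
    image: np.ndarray,
    region_mask: np.ndarray,
    min_diameter_px: float = 2.0,
    max_diameter_px: float = 8.0,
    min_prominence: float = 0.35,
) -> int:
    """Count small hematoxylin-dense puncta within a region.

    ``image`` is a hematoxylin density map or an RGB HE image (which is
    deconvolved first). Detection runs in OD space relative to the
    region's median density, making the count invariant to uniform
    brightness changes of the RGB image. Blobs are size-banded by
    equivalent diameter.
    """
    if not 0 < min_diameter_px < max_diameter_px:
        raise ValueError("need 0 < min_diameter_px < max_diameter_px")
    img = np.asarray(image)
    if img.ndim == 3:
        hema = deconvolve_he(img).hematoxylin
    else:
        hema = np.asarray(img, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    background = float(np.median(hema[region_mask]))
    dense = (hema > background + min_prominence) & region_mask
    from scipy import ndimage as ndi

    labels, n = ndi.label(dense)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    diameters = 2.0 * np.sqrt(areas / np.pi)
    return int(((diameters >= min_diameter_px) & (diameters <= max_diameter_px)).sum())


@dataclass
class PercentPositive:
    """Percent of marker-positive cells in one immunofluorescence field."""

    percent: float
    n_cells: int
    n_positive: int
    no_cells: bool
    per_cell: pd.DataFrame


def percent_positive_cells(
    if_image: FieldImage,
    marker_threshold: float,
    direction: str = "above",
    measurement: str = "cell",  # "cell" mean or "nuclear" mean
    marker_channel: str = "gfp",
    counterstain_channel: str = "hoechst",
    min_area_px: int = 25,
    max_area_px: int = 5000,
    ring_width_px: float = 5.0,
    background_subtract: bool = True,
) -> PercentPositive:
    """Percent of cells whose marker measurement crosses a threshold.

    Nuclei are segmented from the counterstain (DAPI/Hoechst) channel; the
    marker is read as nuclear mean (direction "below" for HMGB1 loss) or
    whole-cell mean (direction "above" for CASP-3a, p-eIF2a, CD3, F4/80).
    Returns a per-cell table suitable for one-dot-per-view-field plots.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    if measurement not in ("cell", "nuclear"):
        raise ValueError("measurement must be 'cell' or 'nuclear'")
    mask = _segmentation.segment_nuclei(if_image.channels[counterstain_channel])
    mask, _ = _segmentation.filter_debris(mask, min_area_px, max_area_px)
    if len(mask.table) == 0:
        return PercentPositive(
            percent=float("nan"), n_cells=0, n_positive=0, no_cells=True,
            per_cell=pd.DataFrame(columns=["cell_id", "value", "positive"]),
        )
    rois = _segmentation.build_cytoplasm_rois(mask, ring_width_px)
    marker = np.asarray(if_image.channels[marker_channel], dtype=float)
    if background_subtract:
        marker = _features.subtract_background(marker)
    rows = []
    for cid in rois.cell_ids:
        cid = int(cid)
        nuc = rois.nucleus_mask(cid)
        if measurement == "nuclear":
            value = _features.nuclear_mean_intensity(marker, nuc)
        else:
            value = _features.cell_mean_intensity(marker, nuc, rois.cytoplasm_mask(cid))
        positive = value > marker_threshold if direction == "above" else value < marker_threshold
        rows.append(dict(cell_id=cid, value=value, positive=bool(positive)))
    per_cell = pd.DataFrame(rows)
    n_pos = int(per_cell.positive.sum())
    return PercentPositive(
        percent=100.0 * n_pos / len(per_cell),
        n_cells=len(per_cell),
        n_positive=n_pos,
        no_cells=False,
        per_cell=per_cell,
    )
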