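"""Seeded synthetic-data generators with per-cell ground truth.

Emulates the raw data of a high-content immunogenic-cell-death (ICD) screen:

* fluorescence view fields of U2OS-like cells carrying one of four
  biosensors (CALR-GFP aggregation, quinacrine-stained ATP vesicles,
  nuclear HMGB1-GFP, MX1-promoter GFP), with Hoechst and PI channels;
* flow-cytometry-like event tables (PI viability + surface-CALR marker);
* HE-stained tissue images with a necrotic low-hematoxylin region and
  planted leukocyte puncta.

Every generator is driven by a single integer seed and records its latent
labels (responder flags, granule centers, necrotic area, leukocyte
positions) so downstream quantification can be validated against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .calibration import gaussian_intersection

ASSAYS = ("CALR_GFP", "QUINACRINE", "HMGB1_GFP", "MX1_GFP")

#: assays whose readout is cytoplasmic granularity
GRANULARITY_ASSAYS = ("CALR_GFP", "QUINACRINE")


class FieldPlacementError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be placed in the image."""


@dataclass
class IntensityParams:
    """Photon-budget parameters of the simulated sCMOS acquisition.

    All levels are expected photon counts per pixel; channels are rendered
    as background + additive foreground, then Poisson shot noise and
    Gaussian read noise are applied.
    """

    hoechst_background: float = 40.0
    gfp_background: float = 20.0
    pi_background: float = 30.0
    hoechst_level: float = 600.0        # live nucleus above background
    dead_hoechst_factor: float = 1.8    # chromatin condensation brightening
    pi_dead_level: float = 3000.0       # PI influx into dead nuclei
    cytoplasm_diffuse: float = 100.0    # diffuse biosensor level in cytoplasm
    granule_amplitude: float = 40.0     # peak height of one granule
    hmgb1_nuclear_level: float = 300.0  # retained nuclear HMGB1-GFP
    hmgb1_released_factor: float = 0.2  # nuclear level after exodus
    hmgb1_cytoplasm_level: float = 30.0
    mx1_level: float = 30.0             # basal whole-cell MX1-GFP
    mx1_positive_factor: float = 10.0   # induction fold change
    debris_level: float = 500.0
    read_noise_sd: float = 3.0


@dataclass
class FieldSpec:
    """Specification of one simulated microscopy view field."""

    n_cells: int = 80
    image_shape: tuple[int, int] = (400, 400)
    nucleus_radius_mean: float = 7.0
    nucleus_radius_sd: float = 0.8
    cytoplasm_extent_px: float = 5.0
    outer_margin_px: float = 3.0  # biosensor rendered this far beyond the ROI ring
    assay: str = "CALR_GFP"
    responder_fraction: float = 0.3
    dead_fraction: float = 0.05
    granule_count: int = 12
    granule_sigma_px: float = 1.5
    n_debris: int = 0
    min_gap_px: float = 14.0
    intensity: IntensityParams = field(default_factory=IntensityParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.granule_count < 0:
            raise ValueError("granule_count must be >= 0")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus_radius_mean must be > 0")


@dataclass
class FieldImage:
    """One acquired view field: named 2-D channels plus plate metadata."""

    channels: dict[str, np.ndarray]
    well: str = "A01"
    field: int = 0
    assay: str = "CALR_GFP"

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """Latent labels of a generated image.

    ``cells`` has one row per generated cell (cell_id, y, x, radius_px,
    dead, responder, granule_count); ``granules`` one row per rendered
    granule center. Tissue images populate the scalar fields instead.
    """

    cells: pd.DataFrame
    granules: Optional[pd.DataFrame] = None
    necrotic_area_fraction: Optional[float] = None
    leukocyte_count: Optional[int] = None
    leukocyte_centers: Optional[pd.DataFrame] = None
    hematoxylin_density: Optional[np.ndarray] = None
    eosin_density: Optional[np.ndarray] = None
    necrotic_mask: Optional[np.ndarray] = None


_EMPTY_CELLS = {
    "cell_id": pd.Series(dtype=int),
    "y": pd.Series(dtype=float),
    "x": pd.Series(dtype=float),
    "radius_px": pd.Series(dtype=float),
    "dead": pd.Series(dtype=bool),
    "responder": pd.Series(dtype=bool),
    "granule_count": pd.Series(dtype=int),
}


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radii: np.ndarray,
    margin_extra: float,
    gap: float,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Rejection-sample non-overlapping centers; raises FieldPlacementError."""
    H, W = shape
    centers = np.empty((n, 2))
    for i in range(n):
        m = radii[i] + margin_extra
        if 2 * m >= min(H, W):
            raise FieldPlacementError("image too small for requested cell size")
        attempts = 0
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise FieldPlacementError(
                    f"could not place {n} non-overlapping nuclei in {shape} "
                    f"after {max_attempts} attempts"
                )
            c = rng.uniform([m, m], [H - m, W - m])
            if i == 0:
                break
            d = np.hypot(*(centers[:i] - c).T)
            if np.all(d > radii[:i] + radii[i] + gap):
                break
        centers[i] = c
    return centers


def _patch(shape: tuple[int, int], cy: float, cx: float, reach: float):
    H, W = shape
    y0 = max(int(math.floor(cy - reach)) - 1, 0)
    y1 = min(int(math.ceil(cy + reach)) + 2, H)
    x0 = max(int(math.floor(cx - reach)) - 1, 0)
    x1 = min(int(math.ceil(cx + reach)) + 2, W)
    return slice(y0, y1), slice(x0, x1)


def _ellipse_mask(sy: slice, sx: slice, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[sy, sx]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _disk_mask(sy: slice, sx: slice, cy, cx, r) -> np.ndarray:
    yy, xx = np.mgrid[sy, sx]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_field(spec: FieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one view field and its ground truth.

    Returns 16-bit channels ``hoechst``, ``gfp`` and ``pi``. The ``gfp``
    channel carries whichever biosensor ``spec.assay`` selects (quinacrine
    vesicles are rendered as GFP-like puncta). Dead cells have condensed,
    brighter nuclei and an elevated PI channel. Bit-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    ip = spec.intensity

    hoechst = np.full((H, W), ip.hoechst_background, dtype=float)
    gfp = np.full((H, W), ip.gfp_background, dtype=float)
    pi = np.full((H, W), ip.pi_background, dtype=float)

    n = spec.n_cells
    radii = np.clip(
        rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd, n), 3.0, None
    )
    aspect = rng.uniform(0.85, 1.15, n)
    thetas = rng.uniform(0, math.pi, n)
    centers = (
        _place_centers(
            rng,
            n,
            (H, W),
            radii,
            spec.cytoplasm_extent_px + spec.outer_margin_px + 2.0,
            spec.min_gap_px,
        )
        if n
        else np.empty((0, 2))
    )
    dead = rng.random(n) < spec.dead_fraction
    responder = rng.random(n) < spec.responder_fraction
    if spec.assay == "CALR_GFP":
        granular = responder.copy()
    elif spec.assay == "QUINACRINE":
        granular = ~responder  # untreated cells keep their ATP vesicles
    else:
        granular = np.zeros(n, dtype=bool)

    rows = []
    granule_rows: list[tuple[int, float, float]] = []
    for i in range(n):
        cy, cx = centers[i]
        ry, rx = radii[i] * aspect[i], radii[i] / aspect[i]
        r_eff = max(ry, rx)
        shrink = 0.7 if dead[i] else 1.0
        reach = r_eff + spec.cytoplasm_extent_px + spec.outer_margin_px
        sy, sx = _patch((H, W), cy, cx, reach)
        nuc = _ellipse_mask(sy, sx, cy, cx, ry * shrink, rx * shrink, thetas[i])
        full_nuc = _ellipse_mask(sy, sx, cy, cx, ry, rx, thetas[i])
        # annulus where granules live (matches the measured ROI ring) and
        # the larger footprint over which diffuse biosensor is rendered, so
        # small segmentation-boundary errors never reach background pixels
        annulus = _disk_mask(sy, sx, cy, cx, r_eff + spec.cytoplasm_extent_px) & ~full_nuc
        footprint = _disk_mask(sy, sx, cy, cx, reach)
        cyto = footprint & ~full_nuc

        hoechst[sy, sx][nuc] += ip.hoechst_level * (
            ip.dead_hoechst_factor if dead[i] else 1.0
        )
        if dead[i]:
            pi[sy, sx][nuc] += ip.pi_dead_level

        g_count = 0
        if spec.assay in GRANULARITY_ASSAYS:
            # diffuse signal covers the whole footprint (2-D projection of
            # the ER/vesicle compartment extends over the nucleus as well)
            contrib = np.where(footprint, ip.cytoplasm_diffuse, 0.0)
            if granular[i] and spec.granule_count > 0 and annulus.any():
                g_count = spec.granule_count
                ys, xs = np.nonzero(annulus)
                pick = rng.integers(0, len(ys), g_count)
                jit = rng.uniform(-0.5, 0.5, (g_count, 2))
                gys = ys[pick] + jit[:, 0]
                gxs = xs[pick] + jit[:, 1]
                yy, xx = np.mgrid[sy, sx]
                bumps = np.zeros_like(contrib)
                inv2s2 = 1.0 / (2.0 * spec.granule_sigma_px**2)
                for gy, gx in zip(gys, gxs):
                    bumps += np.exp(-(((yy - sy.start) - (gy)) ** 2
                                      + ((xx - sx.start) - (gx)) ** 2) * inv2s2)
                    granule_rows.append((i + 1, gy + sy.start, gx + sx.start))
                contrib = (contrib + ip.granule_amplitude * bumps) * footprint
                # fixed photon budget: same mean cell intensity whether the
                # biosensor is diffuse or aggregated
                contrib *= ip.cytoplasm_diffuse * footprint.sum() / contrib.sum()
            gfp[sy, sx] += contrib
        elif spec.assay == "HMGB1_GFP":
            level = ip.hmgb1_nuclear_level * (
                ip.hmgb1_released_factor if responder[i] else 1.0
            )
            gfp[sy, sx][full_nuc] += level
            gfp[sy, sx][cyto] += ip.hmgb1_cytoplasm_level
        else:  # MX1_GFP: whole-cell induction
            level = ip.mx1_level * (ip.mx1_positive_factor if responder[i] else 1.0)
            gfp[sy, sx][footprint] += level

        rows.append(
            dict(
                cell_id=i + 1,
                y=cy,
                x=cx,
                radius_px=radii[i],
                dead=bool(dead[i]),
                responder=bool(responder[i]),
                granule_count=g_count,
            )
        )

    # debris specks: small bright Hoechst dots, excluded later by area filter
    for _ in range(spec.n_debris):
        for _attempt in range(1000):
            r = rng.uniform(1.0, 1.8)
            cy = rng.uniform(4, H - 4)
            cx = rng.uniform(4, W - 4)
            if n == 0:
                break
            d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            if np.all(d > radii + spec.cytoplasm_extent_px + spec.outer_margin_px + 4):
                break
        sy, sx = _patch((H, W), cy, cx, r)
        hoechst[sy, sx][_disk_mask(sy, sx, cy, cx, r)] += ip.debris_level

    channels = {}
    for name, signal in (("hoechst", hoechst), ("gfp", gfp), ("pi", pi)):
        noisy = rng.poisson(signal).astype(float)
        noisy += rng.normal(0.0, ip.read_noise_sd, signal.shape)
        channels[name] = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    cells = pd.DataFrame(rows) if rows else pd.DataFrame(_EMPTY_CELLS)
    granules = pd.DataFrame(granule_rows, columns=["cell_id", "y", "x"])
    return (
        FieldImage(channels=channels, assay=spec.assay),
        GroundTruth(cells=cells, granules=granules),
    )


# ---------------------------------------------------------------------------
# plates


@dataclass
class LogisticDose:
    """Four-parameter logistic dose-response for the responder fraction."""

    floor: float = 0.02
    ceiling: float = 0.95
    ec50: float = 10.0
    hill: float = 1.5

    def fraction(self, dose: float) -> float:
        if dose <= 0:
            return self.floor
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + (self.ec50 / dose) ** self.hill
        )


def default_plate_layout(
    doses: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
    replicates: int = 3,
    treatment: str = "drug",
) -> pd.DataFrame:
    """24-well layout: 3 negative + 3 positive control wells + 6 doses x 3."""
    rows = []
    wells = [f"{r}{c:02d}" for r in "ABCD" for c in range(1, 7)]
    it = iter(wells)
    for _ in range(replicates):
        rows.append(dict(well=next(it), role="negative_control",
                         treatment="untreated", dose=0.0))
    for _ in range(replicates):
        rows.append(dict(well=next(it), role="positive_control",
                         treatment="positive_control", dose=0.0))
    for dose in doses:
        for _ in range(replicates):
            rows.append(dict(well=next(it), role="treated",
                             treatment=treatment, dose=float(dose)))
    return pd.DataFrame(rows)


@dataclass
class PlateData:
    """Simulated plate: one (FieldImage, GroundTruth) pair per view field."""

    fields: list[tuple[FieldImage, GroundTruth]]
    layout: pd.DataFrame
    well_truth: pd.DataFrame  # well, role, treatment, dose, true_fraction


def generate_plate(
    layout: pd.DataFrame,
    dose_response: LogisticDose | None = None,
    field_spec: FieldSpec | None = None,
    fields_per_well: int = 6,
    positive_control_fraction: float = 0.98,
    seed: int = 0,
) -> PlateData:
    """Simulate every well of a plate layout.

    Each well gets ``fields_per_well`` view fields (six per well by
    default, matching the acquisition design). The well's latent responder
    fraction follows the logistic dose-response for treated wells and the
    curve floor / ``positive_control_fraction`` for control wells.
    """
    dose_response = dose_response or LogisticDose()
    base = field_spec or FieldSpec()
    rng = np.random.default_rng(seed)

    fields = []
    truth_rows = []
    for row in layout.itertuples(index=False):
        role = row.role
        if role == "negative_control":
            p = dose_response.floor
        elif role == "positive_control":
            p = positive_control_fraction
        elif role == "treated":
            p = dose_response.fraction(row.dose)
        else:
            raise ValueError(f"unknown well role {role!r}")
        truth_rows.append(dict(well=row.well, role=role, treatment=row.treatment,
                               dose=row.dose, true_fraction=p))
        for f in range(fields_per_well):
            fs = replace(
                base,
                responder_fraction=p,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, truth = generate_field(fs)
            img.well = row.well
            img.field = f
            fields.append((img, truth))
    return PlateData(fields=fields, layout=layout.copy(),
                     well_truth=pd.DataFrame(truth_rows))


def realized_well_fractions(plate: PlateData) -> pd.DataFrame:
    """Per-well realized ground truth: responder fraction among live cells."""
    rows = []
    per_well: dict[str, list[pd.DataFrame]] = {}
    for img, truth in plate.fields:
        per_well.setdefault(img.well, []).append(truth.cells)
    for well, tables in per_well.items():
        cells = pd.concat(tables, ignore_index=True)
        live = cells[~cells.dead]
        rows.append(
            dict(
                well=well,
                n_cells=len(cells),
                n_live=len(live),
                realized_fraction=float(live.responder.mean()) if len(live) else np.nan,
            )
        )
    return pd.DataFrame(rows).merge(plate.well_truth, on="well")


# ---------------------------------------------------------------------------
# cytometry events


@dataclass
class EventSpec:
    """Mixture model for a PI / surface-CALR event table.

    PI and marker intensities are log-normal: a low live and high dead PI
    component, and negative / positive marker components among live cells
    (dead events draw marker from the negative component).
    """

    n_events: int = 10_000
    live_fraction: float = 0.7
    pi_live_mu: float = math.log(50.0)
    pi_live_sigma: float = 0.4
    pi_dead_mu: float = math.log(2000.0)
    pi_dead_sigma: float = 0.4
    marker_positive_fraction: float = 0.3
    marker_neg_mu: float = math.log(100.0)
    marker_neg_sigma: float = 0.35
    marker_pos_mu: float = math.log(1000.0)
    marker_pos_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        for name in ("live_fraction", "marker_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("pi_live_sigma", "pi_dead_sigma",
                     "marker_neg_sigma", "marker_pos_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def true_pi_boundary(self) -> float:
        """Equal-likelihood boundary of the two PI components (linear scale)."""
        return math.exp(
            gaussian_intersection(self.pi_live_mu, self.pi_live_sigma,
                                  self.pi_dead_mu, self.pi_dead_sigma)
        )

    def true_marker_boundary(self) -> float:
        return math.exp(
            gaussian_intersection(self.marker_neg_mu, self.marker_neg_sigma,
                                  self.marker_pos_mu, self.marker_pos_sigma)
        )


def generate_events(spec: EventSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an event table; returns (events, truth).

    ``events`` columns: event_id, PI, marker. ``truth`` columns: event_id,
    live, marker_positive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    live = rng.random(n) < spec.live_fraction
    pi = np.where(
        live,
        rng.lognormal(spec.pi_live_mu, spec.pi_live_sigma, n),
        rng.lognormal(spec.pi_dead_mu, spec.pi_dead_sigma, n),
    )
    positive = live & (rng.random(n) < spec.marker_positive_fraction)
    marker = np.where(
        positive,
        rng.lognormal(spec.marker_pos_mu, spec.marker_pos_sigma, n),
        rng.lognormal(spec.marker_neg_mu, spec.marker_neg_sigma, n),
    )
    events = pd.DataFrame(
        dict(event_id=np.arange(1, n + 1), PI=pi, marker=marker)
    )
    truth = pd.DataFrame(
        dict(event_id=events.event_id, live=live, marker_positive=positive)
    )
    return events, truth


# ---------------------------------------------------------------------------
# HE tissue


@dataclass
class TissueSpec:
    """HE tissue image with a necrotic (hematoxylin-poor, eosin-rich) disc."""

    image_shape: tuple[int, int] = (512, 512)
    necrotic_fraction: float = 0.25
    hematoxylin_inside: float = 0.12
    hematoxylin_outside: float = 0.7
    eosin_inside: float = 0.8
    eosin_outside: float = 0.4
    density_noise_sd: float = 0.05
    noise_smooth_px: float = 2.0
    n_leukocytes: int = 40
    leukocyte_radius_px: float = 2.5
    leukocyte_density: float = 1.3
    leukocyte_min_sep_px: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.necrotic_fraction < 1.0:
            raise ValueError("necrotic_fraction must be in [0, 1)")
        H, W = self.image_shape
        if self.necrotic_fraction > 0:
            r = math.sqrt(self.necrotic_fraction * H * W / math.pi)
            if 2 * r >= min(H, W):
                raise ValueError(
                    "requested necrotic disc does not fit in the image"
                )
        if self.n_leukocytes < 0:
            raise ValueError("n_leukocytes must be >= 0")


def _smooth_noise(rng, shape, sd, smooth):
    noise = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), smooth)
    s = noise.std()
    if s > 0:
        noise *= sd / s
    return noise


def generate_he_tissue(spec: TissueSpec) -> tuple[np.ndarray, GroundTruth]:
    """Compose an RGB HE image via Beer-Lambert absorption.

    Hematoxylin and eosin density maps (optical-density units) are built
    from the necrotic-disc geometry plus smooth noise, leukocytes are
    planted as small hematoxylin-dense discs, and the RGB image is
    ``I = 256 * 10^(-D @ S) - 1`` on the standard HE stain basis.
    """
    from .histology import HE_STAIN_MATRIX, recompose_he

    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    yy, xx = np.mgrid[0:H, 0:W]

    if spec.necrotic_fraction > 0:
        r = math.sqrt(spec.necrotic_fraction * H * W / math.pi)
        necrotic = (yy - H / 2.0) ** 2 + (xx - W / 2.0) ** 2 <= r * r
    else:
        necrotic = np.zeros((H, W), dtype=bool)
    realized = float(necrotic.mean())
    if spec.necrotic_fraction > 0 and abs(realized - spec.necrotic_fraction) > 0.01:
        raise RuntimeError("rasterized necrotic fraction off by more than 1%")

    hema = np.where(necrotic, spec.hematoxylin_inside, spec.hematoxylin_outside)
    eosin = np.where(necrotic, spec.eosin_inside, spec.eosin_outside)
    hema = hema + _smooth_noise(rng, (H, W), spec.density_noise_sd, spec.noise_smooth_px)
    eosin = eosin + _smooth_noise(rng, (H, W), spec.density_noise_sd, spec.noise_smooth_px)

    centers = []
    margin = spec.leukocyte_radius_px + 2
    attempts = 0
    while len(centers) < spec.n_leukocytes:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place leukocytes with requested separation")
        c = rng.uniform([margin, margin], [H - margin, W - margin])
        if all(np.hypot(c[0] - y0, c[1] - x0) >= spec.leukocyte_min_sep_px
               for y0, x0 in centers):
            centers.append((c[0], c[1]))
    for cy, cx in centers:
        sy, sx = _patch((H, W), cy, cx, spec.leukocyte_radius_px)
        disk = _disk_mask(sy, sx, cy, cx, spec.leukocyte_radius_px)
        hema[sy, sx][disk] += spec.leukocyte_density

    hema = np.clip(hema, 0.0, None)
    eosin = np.clip(eosin, 0.0, None)
    rgb = recompose_he(hema, eosin, HE_STAIN_MATRIX)

    truth = GroundTruth(
        cells=pd.DataFrame(_EMPTY_CELLS),
        necrotic_area_fraction=realized,
        leukocyte_count=len(centers),
        leukocyte_centers=pd.DataFrame(centers, columns=["y", "x"]),
        hematoxylin_density=hema,
        eosin_density=eosin,
        necrotic_mask=necrotic,
    )
    return rgb, truth
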