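"""End-to-end plate analysis: simulate -> segment -> measure -> calibrate
-> summarize -> stats, deterministic for a fixed seed.

The run writes a per-cell CSV, a thresholds JSON, a well-summary CSV, a
dose-response stats CSV and a run manifest recording parameters and stage
counts. Calibration uses the plate's negative and positive control wells;
when no positive controls exist it falls back to the k-sigma rule with a
warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    ASSAY_FEATURES,
    ThresholdModel,
    default_direction,
    dose_response_table,
    feature_column,
    fit_threshold,
    summarize_plate,
)
from .evaluation import well_ci_coverage
from .io import read_layout
from .segmentation import build_cytoplasm_rois, filter_debris, segment_nuclei
from .features import measure_field
from .synthetic import (
    FieldSpec,
    LogisticDose,
    PlateData,
    default_plate_layout,
    generate_plate,
    realized_well_fractions,
)

log = logging.getLogger("icd_profiler")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters of one reproducible plate run."""

    assay: str = "CALR_GFP"
    seed: int = 0
    out_dir: str = "results/run"
    layout_path: Optional[str] = None
    fields_per_well: int = 6
    n_cells_per_field: int = 80
    image_shape: tuple[int, int] = (400, 400)
    dose_response: LogisticDose = field(default_factory=LogisticDose)
    dead_fraction: float = 0.05
    min_area_px: int = 25
    max_area_px: int = 5000
    ring_width_px: float = 5.0
    min_distance_px: int = 7
    block_px: int = 4
    pi_threshold: float = 500.0
    calibration_method: str = "intersection"
    k_sigma: float = 3.0
    min_live: int = 50
    n_debris_per_field: int = 0

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "dose_response" in raw and isinstance(raw["dose_response"], dict):
            raw["dose_response"] = LogisticDose(**raw["dose_response"])
        if "image_shape" in raw:
            raw["image_shape"] = tuple(raw["image_shape"])
        return cls(**raw)


@dataclass
class RunResult:
    """Paths of the result bundle plus the in-memory tables."""

    records: pd.DataFrame
    well_summaries: pd.DataFrame
    stats: pd.DataFrame
    model: ThresholdModel
    manifest: dict
    paths: dict[str, Path]
    plate: Optional[PlateData] = None


def _simulate(config: RunConfig) -> PlateData:
    layout = (
        read_layout(config.layout_path)
        if config.layout_path
        else default_plate_layout()
    )
    spec = FieldSpec(
        n_cells=config.n_cells_per_field,
        image_shape=config.image_shape,
        assay=config.assay,
        dead_fraction=config.dead_fraction,
        n_debris=config.n_debris_per_field,
    )
    return generate_plate(
        layout,
        dose_response=config.dose_response,
        field_spec=spec,
        fields_per_well=config.fields_per_well,
        seed=config.seed,
    )


def measure_plate(plate: PlateData, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Segment and measure every field; returns pooled records and counts."""
    all_records = []
    all_qc = []
    n_segmented = 0
    n_debris_removed = 0
    for img, _truth in plate.fields:
        mask = segment_nuclei(
            img.channels["hoechst"], min_distance_px=config.min_distance_px
        )
        n_segmented += len(mask.table)
        mask, removed = filter_debris(
            mask, min_area_px=config.min_area_px, max_area_px=config.max_area_px
        )
        n_debris_removed += removed
        rois = build_cytoplasm_rois(mask, ring_width_px=config.ring_width_px)
        records, qc = measure_field(
            img,
            rois,
            config.assay,
            pi_threshold=config.pi_threshold,
            block_px=config.block_px,
        )
        all_records.append(records)
        all_qc.append(qc)
    records = pd.concat(all_records, ignore_index=True)
    qc = pd.concat(all_qc, ignore_index=True)
    counts = dict(
        n_fields=len(plate.fields),
        n_segmented=n_segmented,
        n_debris_removed=n_debris_removed,
        n_cells_measured=len(records),
        n_qc_excluded=len(qc),
    )
    return records, counts


def calibrate_from_controls(
    records: pd.DataFrame, layout: pd.DataFrame, config: RunConfig
) -> ThresholdModel:
    """Fit the assay threshold from the plate's control wells."""
    col = feature_column(config.assay)
    direction = default_direction(config.assay)
    merged = records.merge(layout[["well", "role"]], on="well")
    live = merged[merged["live"].astype(bool)]
    ok = live[np.isfinite(live[col].to_numpy(dtype=float))]
    neg = ok[ok.role == "negative_control"][col].to_numpy()
    pos = ok[ok.role == "positive_control"][col].to_numpy()
    if config.calibration_method == "k_sigma" or len(pos) == 0:
        if config.calibration_method != "k_sigma":
            log.warning(
                "no positive-control cells: falling back to k_sigma thresholding"
            )
        return fit_threshold(
            neg, direction=direction, method="k_sigma", k=config.k_sigma,
            assay=config.assay,
        )
    return fit_threshold(
        neg, pos, direction=direction, method="intersection", assay=config.assay
    )


def run_plate_analysis(config: RunConfig) -> RunResult:
    """Run the full simulated-plate analysis and write the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        plate = _simulate(config)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"simulate: {e}") from e

    try:
        records, counts = measure_plate(plate, config)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"measure: {e}") from e

    try:
        model = calibrate_from_controls(records, plate.layout, config)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"calibrate: {e}") from e

    try:
        summaries = summarize_plate(
            records, model, plate.layout, min_live=config.min_live
        )
        realized = realized_well_fractions(plate)
        coverage = well_ci_coverage(summaries, realized)
        summaries = summaries.merge(
            realized[["well", "realized_fraction"]], on="well", how="left"
        )
        summaries = summaries.merge(
            realized[["well", "true_fraction"]].rename(
                columns={"true_fraction": "latent_fraction"}
            ),
            on="well",
            how="left",
        )
        stats = dose_response_table(summaries)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"summarize: {e}") from e

    for well, grp in summaries.groupby("well"):
        log.info(
            "well %s: %d cells, %d live%s",
            well,
            int(grp.n_cells.iloc[0]),
            int(grp.n_live.iloc[0]),
            " (insufficient viable cells)"
            if bool(grp.insufficient_viable_cells.iloc[0])
            else "",
        )

    paths = dict(
        records=out / "per_cell.csv",
        wells=out / "well_summary.csv",
        stats=out / "stats.csv",
        thresholds=out / "thresholds.json",
        manifest=out / "manifest.json",
        coverage=out / "truth_coverage.csv",
    )
    records.to_csv(paths["records"], index=False, float_format="%.8g")
    summaries.to_csv(paths["wells"], index=False, float_format="%.8g")
    stats.to_csv(paths["stats"], index=False, float_format="%.8g")
    coverage.to_csv(paths["coverage"], index=False, float_format="%.8g")

    model_dict = {
        k: (None if v is None else v) for k, v in dataclasses.asdict(model).items()
    }
    paths["thresholds"].write_text(json.dumps(model_dict, indent=1, sort_keys=True))

    manifest = dict(
        package_version=__version__,
        seed=config.seed,
        assay=config.assay,
        parameters={
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (dict,))
        },
        stage_counts=counts,
        n_wells=int(summaries.well.nunique()),
        n_wells_insufficient=int(summaries.insufficient_viable_cells.sum()),
    )
    paths["manifest"].write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )

    return RunResult(
        records=records,
        well_summaries=summaries,
        stats=stats,
        model=model,
        manifest=manifest,
        paths=paths,
        plate=plate,
    )
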