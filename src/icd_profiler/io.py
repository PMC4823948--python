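"""Readers and writers for the pipeline's interchange formats.

View fields travel as multi-page 16-bit TIFF (one page per channel, page
order recorded in a JSON sidecar together with any ground truth); event
tables and object tables as CSV; tissue images as PNG/TIFF RGB.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import FieldImage, GroundTruth

CHANNEL_ORDER = ("hoechst", "gfp", "pi")


def write_field_tiff(
    field: FieldImage, path: str | Path, truth: Optional[GroundTruth] = None
) -> Path:
    """Write a field as multi-page TIFF plus a JSON sidecar of metadata."""
    path = Path(path)
    names = [c for c in CHANNEL_ORDER if c in field.channels]
    names += [c for c in field.channels if c not in names]
    stack = np.stack([field.channels[c] for c in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = dict(channels=names, well=field.well, field=field.field, assay=field.assay)
    if truth is not None:
        meta["ground_truth"] = dict(
            cells=truth.cells.to_dict(orient="list"),
            granules=(
                truth.granules.to_dict(orient="list")
                if truth.granules is not None
                else None
            ),
        )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_field_tiff(path: str | Path) -> FieldImage:
    """Read a multi-page TIFF field written by :func:`write_field_tiff`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = meta["channels"]
        well, fld, assay = meta["well"], meta["field"], meta["assay"]
    else:
        names = list(CHANNEL_ORDER[: len(stack)])
        well, fld, assay = "A01", 0, "CALR_GFP"
    channels = {name: stack[i] for i, name in enumerate(names)}
    return FieldImage(channels=channels, well=well, field=fld, assay=assay)


def write_events_csv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = {"event_id", "PI", "marker"} - set(events.columns)
    if missing:
        raise ValueError(f"event table lacks columns {sorted(missing)}")
    return events


def write_tissue_image(rgb: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))
    return path


def read_tissue_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path)
    missing = {"well", "role", "treatment", "dose"} - set(layout.columns)
    if missing:
        raise ValueError(f"plate layout lacks columns {sorted(missing)}")
    return layout
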