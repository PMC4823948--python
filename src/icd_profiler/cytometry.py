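"""Event-table gating: PI viability gate and surface-CALR positivity.

The analysis is limited to living (PI-negative) events; the positive
fraction of a marker among live events is reported with a Clopper-Pearson
exact 95% confidence interval. The automatic PI threshold reuses the
two-Gaussian intersection rule on log-transformed intensities, where both
live and dead populations are close to log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from statsmodels.stats.proportion import proportion_confint

from .calibration import ThresholdModel, gaussian_intersection


def gate_live(
    events: pd.DataFrame, pi_threshold: float, pi_column: str = "PI"
) -> tuple[pd.DataFrame, float]:
    """Retain events with PI below the threshold; return (subset, fraction)."""
    if pi_threshold <= 0:
        raise ValueError("pi_threshold must be > 0")
    if pi_column not in events.columns:
        raise ValueError(f"event table lacks a {pi_column!r} column")
    pi = events[pi_column].to_numpy(dtype=float)
    if np.isnan(pi).any():
        raise ValueError("PI column contains missing values")
    keep = pi < pi_threshold
    fraction = float(keep.mean()) if len(events) else 0.0
    return events[keep].copy(), fraction


def auto_pi_threshold(events: pd.DataFrame, pi_column: str = "PI") -> float:
    """Two-Gaussian intersection threshold fitted on log PI intensities.

    The bimodal log-intensity histogram is split with Otsu, a Gaussian is
    fitted to each side, and the equal-likelihood intersection is returned
    on the linear intensity scale.
    """
    pi = events[pi_column].to_numpy(dtype=float)
    pi = pi[pi > 0]
    if len(pi) < 40:
        raise ValueError("need >= 40 positive PI values to fit a threshold")
    logs = np.log(pi)
    split = threshold_otsu(logs)
    lo, hi = logs[logs <= split], logs[logs > split]
    if len(lo) < 20 or len(hi) < 20:
        raise ValueError("PI distribution does not show two populations")
    x = gaussian_intersection(lo.mean(), lo.std(ddof=1), hi.mean(), hi.std(ddof=1))
    return float(np.exp(x))


@dataclass
class PositiveFraction:
    """Marker-positive fraction among live events with its exact 95% CI."""

    fraction: float
    n_positive: int
    n: int
    ci_low: float
    ci_high: float
    mean_marker: float
    insufficient_viable_cells: bool = False


def marker_positive_fraction(
    live_events: pd.DataFrame,
    model: ThresholdModel,
    marker_column: str = "marker",
    min_events: int = 1,
) -> PositiveFraction:
    """Fraction of live events called positive by a calibrated threshold.

    Returns an undefined result flagged ``insufficient_viable_cells`` when
    the live gate retained fewer than ``min_events`` events. Both the
    thresholded fraction and the mean marker intensity are reported.
    """
    n = len(live_events)
    if n < min_events or n == 0:
        return PositiveFraction(
            fraction=float("nan"), n_positive=0, n=n,
            ci_low=float("nan"), ci_high=float("nan"),
            mean_marker=float("nan"), insufficient_viable_cells=True,
        )
    values = live_events[marker_column].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("marker column contains missing values")
    calls = model.classify(values)
    k = int(calls.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return PositiveFraction(
        fraction=k / n, n_positive=k, n=n,
        ci_low=float(lo), ci_high=float(hi),
        mean_marker=float(values.mean()),
    )
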