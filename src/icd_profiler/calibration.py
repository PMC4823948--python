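"""Control-calibrated thresholds and group statistics.

Per-assay decision thresholds are derived from the Gaussian distributions
of negative and positive control populations: either the equal-likelihood
intersection of the two fitted Gaussians (default) or a k-sigma offset
from the negative control when no positive control is available. Group
comparisons use the two-tailed Welch (unequal-variance) t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: assay -> (CellRecord feature column, direction of the positive phenotype)
ASSAY_FEATURES = {
    "CALR_GFP": ("granularity_score", "above"),
    "QUINACRINE": ("granularity_score", "below"),
    "HMGB1_GFP": ("nuclear_biosensor_mean", "below"),
    "MX1_GFP": ("cell_mean_gfp", "above"),
}

MIN_CONTROL_VALUES = 20


def gaussian_intersection(m1: float, s1: float, m2: float, s2: float) -> float:
    """Equal-likelihood point of N(m1, s1) and N(m2, s2) between the means.

    For equal SDs this is the midpoint; otherwise the root of the
    log-density equality that lies between the two means.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if m1 == m2:
        raise ValueError("component means are equal; no separating threshold")
    if math.isclose(s1, s2, rel_tol=1e-12, abs_tol=1e-12):
        return 0.5 * (m1 + m2)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = 2.0 * (m2 / s2**2 - m1 / s1**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 + 2.0 * math.log(s1 / s2)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("no real intersection of the two Gaussians")
    roots = ((-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a))
    lo, hi = sorted((m1, m2))
    inside = [r for r in roots if lo <= r <= hi]
    if inside:
        return float(min(inside, key=lambda r: abs(r - 0.5 * (m1 + m2))))
    # degenerate overlap: fall back to the root nearest the midpoint
    return float(min(roots, key=lambda r: abs(r - 0.5 * (m1 + m2))))


@dataclass
class ThresholdModel:
    """Calibrated per-assay decision threshold with directionality."""

    assay: str
    direction: str  # "above": values above threshold are positive
    neg_mean: float
    neg_sd: float
    threshold: float
    pos_mean: Optional[float] = None
    pos_sd: Optional[float] = None
    method: str = "intersection"
    k: Optional[float] = None

    def classify(self, values) -> np.ndarray:
        """Boolean positivity calls for an array of feature values."""
        v = np.asarray(values, dtype=float)
        if self.direction == "above":
            return v > self.threshold
        return v < self.threshold


def fit_threshold(
    neg_values: Sequence[float],
    pos_values: Optional[Sequence[float]] = None,
    direction: str = "above",
    method: str = "intersection",
    k: float = 3.0,
    assay: str = "",
) -> ThresholdModel:
    """Fit Gaussians to control populations and derive the threshold.

    ``method="intersection"`` places the threshold at the equal-likelihood
    point of the two fitted Gaussians; ``method="k_sigma"`` at
    ``neg_mean ± k·neg_sd`` oriented by ``direction`` (used when no
    positive control exists).
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    neg = np.asarray(neg_values, dtype=float)
    neg = neg[np.isfinite(neg)]
    if len(neg) < MIN_CONTROL_VALUES:
        raise ValueError(
            f"need >= {MIN_CONTROL_VALUES} negative-control values, got {len(neg)}"
        )
    neg_mean, neg_sd = float(neg.mean()), float(neg.std(ddof=1))
    if neg_sd == 0:
        raise ValueError("negative control has zero variance")

    if method == "k_sigma":
        thr = neg_mean + k * neg_sd if direction == "above" else neg_mean - k * neg_sd
        return ThresholdModel(assay=assay, direction=direction, neg_mean=neg_mean,
                              neg_sd=neg_sd, threshold=float(thr),
                              method="k_sigma", k=k)
    if method != "intersection":
        raise ValueError(f"unknown method {method!r}")
    if pos_values is None:
        raise ValueError("method='intersection' requires positive-control values")
    pos = np.asarray(pos_values, dtype=float)
    pos = pos[np.isfinite(pos)]
    if len(pos) < MIN_CONTROL_VALUES:
        raise ValueError(
            f"need >= {MIN_CONTROL_VALUES} positive-control values, got {len(pos)}"
        )
    pos_mean, pos_sd = float(pos.mean()), float(pos.std(ddof=1))
    if pos_sd == 0:
        raise ValueError("positive control has zero variance")
    if pos_mean == neg_mean:
        raise ValueError("control means are equal; assay has no separation")
    if direction == "above" and pos_mean < neg_mean:
        raise ValueError("direction='above' but positive control lies below negative")
    if direction == "below" and pos_mean > neg_mean:
        raise ValueError("direction='below' but positive control lies above negative")
    thr = gaussian_intersection(neg_mean, neg_sd, pos_mean, pos_sd)
    return ThresholdModel(assay=assay, direction=direction, neg_mean=neg_mean,
                          neg_sd=neg_sd, pos_mean=pos_mean, pos_sd=pos_sd,
                          threshold=float(thr), method="intersection")


@dataclass
class WellSummary:
    """Per-well aggregate over live cells."""

    well: str
    assay: str
    n_cells: int
    n_live: int
    n_scored: int
    fraction_positive: float  # NaN when insufficient viable cells
    mean_feature: float
    insufficient_viable_cells: bool
    treatment: str = ""
    dose: float = float("nan")


def feature_column(assay: str) -> str:
    try:
        return ASSAY_FEATURES[assay][0]
    except KeyError:
        raise ValueError(f"unknown assay {assay!r}") from None


def default_direction(assay: str) -> str:
    return ASSAY_FEATURES[assay][1]


def summarize_well(
    records: pd.DataFrame,
    model: ThresholdModel,
    min_live: int = 50,
) -> WellSummary:
    """Summarize the pooled cell records of one well.

    The positive fraction is computed over live (PI-negative) cells with a
    defined feature value; wells with fewer than ``min_live`` viable cells
    are flagged and their fraction left undefined, mirroring the caveat
    that near-complete killing leaves too few PI-negative cells to score.
    """
    wells = records["well"].unique()
    if len(wells) > 1:
        raise ValueError(f"records mix wells {sorted(wells)}; pool one well at a time")
    well = str(wells[0]) if len(wells) else ""
    assay = model.assay or (records["assay"].iloc[0] if len(records) else "")
    col = feature_column(assay)
    live = records[records["live"].astype(bool)]
    scored = live[np.isfinite(live[col].to_numpy(dtype=float))]
    n_live = len(live)
    insufficient = n_live < min_live
    if insufficient or len(scored) == 0:
        frac = float("nan")
    else:
        frac = float(model.classify(scored[col].to_numpy()).mean())
    return WellSummary(
        well=well,
        assay=assay,
        n_cells=len(records),
        n_live=n_live,
        n_scored=len(scored),
        fraction_positive=frac,
        mean_feature=float(scored[col].mean()) if len(scored) else float("nan"),
        insufficient_viable_cells=bool(insufficient),
    )


def summarize_plate(
    records: pd.DataFrame,
    model: ThresholdModel,
    layout: pd.DataFrame,
    min_live: int = 50,
) -> pd.DataFrame:
    """One WellSummary row per well, joined with the plate layout."""
    rows = []
    for well, grp in records.groupby("well", sort=True):
        s = summarize_well(grp, model, min_live=min_live)
        rows.append(vars(s))
    out = pd.DataFrame(rows).drop(columns=["treatment", "dose"])
    return out.merge(layout, on="well", how="left")


def welch_t_test(group_a: Iterable[float], group_b: Iterable[float]):
    """Two-tailed Welch t-test; returns (t, df, p).

    Satterthwaite degrees of freedom; if both groups have zero variance
    and equal means the comparison is vacuous and p = 1 by convention.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(
            len(a) + len(b) - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Figure-legend star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def dose_response_table(
    summaries: pd.DataFrame,
    value_column: str = "fraction_positive",
    reference_role: str = "negative_control",
    holm: bool = False,
) -> pd.DataFrame:
    """Per-condition mean ± SD with Welch p and stars vs untreated wells.

    ``summaries`` is the output of :func:`summarize_plate`. Wells flagged
    as having insufficient viable cells are excluded. Star coding follows
    the per-comparison convention; an optional Holm correction across
    conditions can be enabled.
    """
    ok = summaries[~summaries["insufficient_viable_cells"].astype(bool)]
    ref = ok[ok["role"] == reference_role][value_column].dropna()
    if len(ref) < 2:
        raise ValueError("need >= 2 usable reference (untreated control) wells")
    rows = []
    for (treatment, dose), grp in ok.groupby(["treatment", "dose"], sort=True):
        vals = grp[value_column].dropna()
        if grp["role"].iloc[0] == reference_role:
            t = df = p = float("nan")
        elif len(vals) >= 2:
            t, df, p = welch_t_test(vals, ref)
        else:
            t = df = p = float("nan")
        rows.append(
            dict(
                treatment=treatment,
                dose=dose,
                role=grp["role"].iloc[0],
                n_wells=len(vals),
                mean=float(vals.mean()) if len(vals) else float("nan"),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                t=t,
                df=df,
                p=p,
            )
        )
    table = pd.DataFrame(rows)
    pcol = table["p"].to_numpy()
    if holm:
        mask = np.isfinite(pcol)
        from statsmodels.stats.multitest import multipletests

        adj = pcol.copy()
        if mask.any():
            adj[mask] = multipletests(pcol[mask], method="holm")[1]
        table["p_adj"] = adj
        pcol = adj
    table["stars"] = [significance_stars(p) for p in pcol]
    return table
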