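"""Recovery checks against the synthetic generators' ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.proportion import proportion_confint


def match_cells(
    truth_cells: pd.DataFrame, measured: pd.DataFrame, max_dist_px: float = 6.0
) -> pd.DataFrame:
    """Match measured cells to ground-truth cells by nearest centroid.

    ``measured`` needs ``y``/``x`` columns (e.g. the segmentation object
    table). Returns the measured table with truth columns suffixed
    ``_true`` for matches within ``max_dist_px``; unmatched rows are
    dropped.
    """
    if len(truth_cells) == 0 or len(measured) == 0:
        return measured.iloc[0:0].copy()
    tree = cKDTree(truth_cells[["y", "x"]].to_numpy())
    d, idx = tree.query(measured[["y", "x"]].to_numpy())
    ok = d <= max_dist_px
    matched = measured[ok].reset_index(drop=True)
    truth = truth_cells.iloc[idx[ok]].reset_index(drop=True)
    truth = truth.add_suffix("_true")
    return pd.concat([matched, truth], axis=1)


def well_ci_coverage(
    well_summaries: pd.DataFrame,
    realized: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Check each well's measured positive fraction against its truth.

    For every usable well the Clopper-Pearson CI of the measured positive
    count is computed and tested for containing the generator's realized
    responder fraction among live cells. Returns one row per well with a
    ``covered`` flag.
    """
    merged = well_summaries.merge(
        realized[["well", "realized_fraction"]], on="well", how="left"
    )
    rows = []
    for row in merged.itertuples(index=False):
        if row.insufficient_viable_cells or not np.isfinite(row.fraction_positive):
            continue
        n = int(row.n_scored)
        k = int(round(row.fraction_positive * n))
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        rows.append(
            dict(
                well=row.well,
                n_scored=n,
                fraction_positive=row.fraction_positive,
                ci_low=lo,
                ci_high=hi,
                realized_fraction=row.realized_fraction,
                covered=bool(lo <= row.realized_fraction <= hi),
            )
        )
    return pd.DataFrame(rows)
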