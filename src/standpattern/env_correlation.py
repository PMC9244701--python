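"""Pearson correlation between per-plot pattern indices and abiotic factors.

Each plot carries a distance from the river channel (DR) plus four abiotic
measurements: groundwater depth (GD), soil moisture (SM), soil conductance
(SC) and pH.  The index-environment table correlates a chosen per-plot
aggregation index (ANN by default) with each factor, pairwise-complete over
plots where both values are present, with two-sided p from the t transform
on n - 2 degrees of freedom.  No multiple-testing adjustment is applied
across the five factors; significance is flagged raw at 0.05 and 0.01.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stand_model import PlotData

logger = logging.getLogger(__name__)

__all__ = ["pearson", "build_correlation_table", "FACTORS"]

#: Factor columns in output order: distance from river, groundwater depth,
#: soil moisture, soil conductance, pH.
FACTORS = ("DR", "GD", "SM", "SC", "pH")
_FACTOR_KEYS = {"GD": "gd", "SM": "sm", "SC": "sc", "pH": "ph"}


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t transform, n - 2 df).

    Pairs with a missing (NaN/None) value on either side are dropped;
    requires at least 3 complete pairs and nonzero variance in both series.
    """
    xa = np.asarray([np.nan if v is None else float(v) for v in x])
    ya = np.asarray([np.nan if v is None else float(v) for v in y])
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    if len(xa) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(xa)}")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def build_correlation_table(
    plots: Sequence[PlotData],
    index_values: Mapping[str, float],
    index_name: str = "ANN",
) -> pd.DataFrame:
    """Correlate a per-plot index with DR, GD, SM, SC and pH.

    ``index_values`` maps plot_id -> index value.  A factor missing on every
    plot is omitted with a warning.  Returns one row per factor with
    columns factor, r, p, sig_05, sig_01.
    """
    usable = [p for p in plots if p.plot_id in index_values]
    if len(usable) < 3:
        raise ValueError("need at least 3 plots with index values")
    idx = [float(index_values[p.plot_id]) for p in usable]

    rows = []
    for factor in FACTORS:
        if factor == "DR":
            series = [p.distance_from_river for p in usable]
        else:
            series = [p.abiotic.get(_FACTOR_KEYS[factor]) for p in usable]
        present = [v for v in series if v is not None and not np.isnan(v)]
        if not present:
            logger.warning("factor %s missing on all plots; column omitted", factor)
            continue
        r, p_val = pearson(idx, series)
        rows.append(
            {
                "index": index_name,
                "factor": factor,
                "r": r,
                "p": p_val,
                "sig_05": p_val < 0.05,
                "sig_01": p_val < 0.01,
                "n_pairs": int(
                    sum(v is not None and not np.isnan(v) for v in series)
                ),
            }
        )
    return pd.DataFrame(rows)
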