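"""Standardized effect sizes per tract and the null-interval threshold.

The effect size is Cohen's d with pooled SD (athlete minus control).  Its
significance threshold is the half-width of the (1 - alpha) interval of d in
the absence of a true effect: for two groups of 19 at alpha = 0.05 the normal
approximation gives 1.96 * sqrt(38/361) ~= 0.64, so |d| > 0.64 exceeds what
chance alone produces at those group sizes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tractstats")

BOUND_METHODS = ("normal", "t", "montecarlo")


def cohen_d(x, y) -> float:
    """Pooled-SD standardized mean difference, mean(x) - mean(y).

    Pooled variance uses the (n1 + n2 - 2) denominator.  Returns NaN (with a
    warning) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        warnings.warn("zero pooled SD: effect size undefined")
        return float("nan")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def null_effect_bound(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    method: str = "normal",
    n_sim: int = 100_000,
    seed: int = 0,
) -> float:
    """Half-width of the null (1 - alpha) interval of the effect size.

    ``normal``: z_{1-alpha/2} * sqrt((n1+n2)/(n1*n2)) -- the sampling SD of a
    standardized mean difference with the population scale treated as known.
    ``t``: same with the central t quantile at n1+n2-2 df, which additionally
    absorbs the variability of estimating the pooled SD.
    ``montecarlo``: empirical (1-alpha) quantile of |mean difference| over
    null normal simulations with unit population SD (converges to ``normal``).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    factor = math.sqrt((n1 + n2) / (n1 * n2))
    if method == "normal":
        return float(stats.norm.ppf(1 - alpha / 2) * factor)
    if method == "t":
        return float(stats.t.ppf(1 - alpha / 2, n1 + n2 - 2) * factor)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        diffs = (rng.standard_normal((n_sim, n1)).mean(axis=1)
                 - rng.standard_normal((n_sim, n2)).mean(axis=1))
        return float(np.quantile(np.abs(diffs), 1 - alpha))
    raise ValueError(f"unknown bound method {method!r}; choose from {BOUND_METHODS}")


@dataclass(frozen=True)
class NullBoundSpec:
    """A resolved null-interval specification for given group sizes."""
    n1: int
    n2: int
    alpha: float = 0.05
    method: str = "normal"
    n_sim: int = 100_000
    seed: int = 0

    @property
    def bound(self) -> float:
        return null_effect_bound(self.n1, self.n2, self.alpha, self.method,
                                 self.n_sim, self.seed)


# Cross-modality "average" summaries are taken over the four metrics both
# modalities share.
SHARED_SUBMETRICS = ("FA", "MD", "AD", "RD")


def effect_map(
    panel: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "normal",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tract d for every metric, flagged against the null bound.

    Returns ``(rows, summary)``: rows carry (metric, tract_id, d, bound,
    exceeds_null); summary carries per-metric mean |d| and mean signed d plus
    two cross-metric averages, ``DTI_average`` and ``DKI_average``, computed
    over the shared FA/MD/AD/RD sub-metrics only.  The bound is resolved per
    metric from that metric's retained group sizes.  Tracts with zero pooled
    SD are excluded from the map.
    """
    from .ranktests import metric_matrix
    rows = []
    for metric in pd.unique(panel["metric"]):
        values, is_g1, _, tract_ids = metric_matrix(panel, metric)
        n1 = int(is_g1.sum())
        n2 = int((~is_g1).sum())
        if n1 < 2 or n2 < 2:
            logger.warning("%s: a group has <2 subjects; excluded from map", metric)
            continue
        bound = null_effect_bound(n1, n2, alpha, method, seed=seed)
        g1 = values[is_g1]
        g2 = values[~is_g1]
        for j, tract in enumerate(tract_ids):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = cohen_d(g1[:, j], g2[:, j])
            if not np.isfinite(d):
                logger.warning("%s tract %s: zero pooled SD; excluded", metric, tract)
                continue
            rows.append({
                "metric": metric, "tract_id": tract, "d": d, "bound": bound,
                "exceeds_null": bool(abs(d) > bound),
            })
    rows_df = pd.DataFrame(rows)

    summaries = []
    if not rows_df.empty:
        for metric, sub in rows_df.groupby("metric", sort=False):
            summaries.append({
                "metric": metric,
                "mean_abs_d": float(sub["d"].abs().mean()),
                "mean_d": float(sub["d"].mean()),
                "n_exceeding": int(sub["exceeds_null"].sum()),
                "n_tracts": len(sub),
            })
        for modality in ("DTI", "DKI"):
            shared = [f"{modality}_{s}" for s in SHARED_SUBMETRICS]
            sub = rows_df[rows_df["metric"].isin(shared)]
            if sub.empty:
                continue
            summaries.append({
                "metric": f"{modality}_average",
                "mean_abs_d": float(sub["d"].abs().mean()),
                "mean_d": float(sub["d"].mean()),
                "n_exceeding": int(sub["exceeds_null"].sum()),
                "n_tracts": len(sub),
            })
    return rows_df, pd.DataFrame(summaries)
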