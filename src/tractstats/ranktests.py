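"""Per-tract and whole-white-matter nonparametric group comparison.

Provides tie-corrected Mann-Whitney U tests (exact and asymptotic), per-tract
median/IQR summaries with significance flags, and the "single WM ROI"
summary: each subject's mean metric value over all tracts, compared between
groups with the same rank-sum test.

The U statistic reported is the one attached to the first sample (athletes):
U1 = R1 - n1(n1+1)/2 with R1 the athlete rank sum over midranks.  Tests are
two-sided throughout; a result is significant at level alpha iff p < alpha
(strict).  Medians and IQRs use linear interpolation between order statistics.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tractstats")

# Combined-sample size at or below which "auto" mode runs the exact test.
EXACT_THRESHOLD = 12
# Enumeration guard for tied exact tests: C(16, 8) = 12870 subsets.
_MAX_EXACT_N = 16


def midranks(values) -> np.ndarray:
    """Midranks of a finite 1-D sample: ties get the mean of the spanned ranks,
    so the ranks always sum to n(n+1)/2."""
    a = np.asarray(values, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("midranks expects a non-empty 1-D sample")
    if not np.isfinite(a).all():
        raise ValueError("midranks requires finite values")
    return stats.rankdata(a)


def tie_term(values) -> float:
    """Sum of t^3 - t over tie groups; enters the rank-sum variance."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    counts = counts[counts > 1]
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_variance(n1: int, n2: int, ties: float) -> float:
    """Tie-corrected null variance of the U statistic."""
    n = n1 + n2
    return n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))


def asymptotic_u_pvalue(u, n1: int, n2: int, ties: float):
    """Two-sided normal-approximation p for U, with continuity correction.

    Vectorized over ``u``.  Returns p = 1 when the tie-corrected variance is
    zero (all observations identical).
    """
    u = np.asarray(u, dtype=float)
    mu = n1 * n2 / 2.0
    var = rank_sum_variance(n1, n2, ties)
    if var <= 0:
        return np.ones_like(u) if u.shape else 1.0
    z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
    p = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return p if u.shape else float(p)


@lru_cache(maxsize=32)
def _exact_untied_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U1 without ties, by dynamic programming.

    Entry [u] is the number of the C(n1+n2, n1) equally likely label
    assignments with U1 = u.
    """
    n = n1 + n2
    max_r1 = n1 * n + 0  # loose bound on rank sum
    # f[k][s]: subsets of {1..n} of size k with rank sum s
    f = np.zeros((n1 + 1, max_r1 + 1), dtype=float)
    f[0, 0] = 1.0
    for j in range(1, n + 1):
        for k in range(min(j, n1), 0, -1):
            f[k, j:] += f[k - 1, :-j] if j else f[k - 1, :]
    r1 = f[n1]
    offset = n1 * (n1 + 1) // 2
    return r1[offset: offset + n1 * n2 + 1]  # index = U1


def _exact_p_from_distribution(counts: np.ndarray, u_obs: float) -> float:
    total = counts.sum()
    u_grid = np.arange(counts.size, dtype=float)
    p_le = counts[u_grid <= u_obs + 1e-9].sum() / total
    p_ge = counts[u_grid >= u_obs - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _exact_tied_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    us = np.fromiter(
        (sum(c) - offset for c in itertools.combinations(ranks, n1)),
        dtype=float,
        count=math.comb(n, n1),
    )
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float            # statistic for the first sample
    p: float            # two-sided
    n1: int
    n2: int
    mode: str           # "exact" or "asymptotic"
    degenerate: bool    # all values identical across both samples


def mann_whitney(x, y, mode: str = "auto",
                 exact_threshold: int = EXACT_THRESHOLD) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test from midranks.

    ``mode`` is ``"exact"`` (enumeration of all C(n1+n2, n1) label
    assignments), ``"asymptotic"`` (tie-corrected normal approximation with
    continuity correction), or ``"auto"`` (exact when n1+n2 <= exact_threshold).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    combined = np.concatenate([x, y])
    ranks = midranks(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    ties = tie_term(combined)
    degenerate = np.unique(combined).size == 1

    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= exact_threshold)
    if use_exact and n1 + n2 > _MAX_EXACT_N and ties > 0:
        logger.warning(
            "exact test with ties infeasible at n=%d; using asymptotic", n1 + n2)
        use_exact = False

    if degenerate:
        return MannWhitneyResult(u, 1.0, n1, n2,
                                 "exact" if use_exact else "asymptotic", True)
    if use_exact:
        if ties == 0:
            p = _exact_p_from_distribution(_exact_untied_distribution(n1, n2), u)
        else:
            p = _exact_tied_p(ranks, n1, u)
        return MannWhitneyResult(u, p, n1, n2, "exact", False)
    p = float(asymptotic_u_pvalue(u, n1, n2, ties))
    return MannWhitneyResult(u, p, n1, n2, "asymptotic", False)


# ---------------------------------------------------------------------------
# Panel-level comparisons
# ---------------------------------------------------------------------------

def _iqr(a: np.ndarray) -> float:
    lo, hi = np.percentile(a, [25, 75], method="linear")
    return float(hi - lo)


def metric_matrix(panel: pd.DataFrame, metric: str
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Subjects-by-tracts value matrix for one metric, listwise complete.

    Returns ``(values, is_group1, subject_ids, tract_ids)``; subjects missing
    any tract for the metric are dropped (logged).
    """
    sub = panel[panel["metric"] == metric]
    if sub.empty:
        raise KeyError(f"metric {metric!r} absent from panel")
    wide = sub.pivot(index="subject_id", columns="tract_id", values="value")
    complete = wide.dropna()
    dropped = wide.shape[0] - complete.shape[0]
    if dropped:
        logger.info("%s: dropped %d subject(s) with partial tract coverage",
                    metric, dropped)
    groups = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
    groups = groups.loc[complete.index]
    from .synthetic import ATHLETE
    return (complete.to_numpy(dtype=float),
            (groups == ATHLETE).to_numpy(),
            complete.index.to_numpy(),
            complete.columns.to_numpy())


def compare_tracts(panel: pd.DataFrame, alphas=(0.05, 0.01),
                   mode: str = "auto") -> pd.DataFrame:
    """Per-(metric, tract) rank-sum comparison of the two groups.

    One row per metric x tract with group medians/IQRs, the U statistic, the
    two-sided p, and one strict ``significant_<alpha>`` flag per level.
    Tracts observed in only one group are excluded with a warning.
    """
    rows = []
    for metric in pd.unique(panel["metric"]):
        values, is_g1, _, tract_ids = metric_matrix(panel, metric)
        n1 = int(is_g1.sum())
        n2 = int((~is_g1).sum())
        if n1 < 2 or n2 < 2:
            warnings.warn(
                f"{metric}: a group has <2 complete subjects; metric skipped")
            continue
        g1 = values[is_g1]
        g2 = values[~is_g1]
        for j, tract in enumerate(tract_ids):
            res = mann_whitney(g1[:, j], g2[:, j], mode=mode)
            row = {
                "metric": metric,
                "tract_id": tract,
                "n1": n1,
                "n2": n2,
                "median_g1": float(np.median(g1[:, j])),
                "iqr_g1": _iqr(g1[:, j]),
                "median_g2": float(np.median(g2[:, j])),
                "iqr_g2": _iqr(g2[:, j]),
                "U": res.U,
                "p": res.p,
                "degenerate": res.degenerate,
            }
            for a in alphas:
                row[f"significant_{a}"] = bool(res.p < a)
            rows.append(row)
    return pd.DataFrame(rows)


def subject_roi_means(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-subject single-WM-ROI value: the mean over all tracts of a metric.

    Subjects with partial tract coverage for a metric are dropped for that
    metric.  Returns long rows (subject_id, group, metric, roi_value).
    """
    frames = []
    for metric in pd.unique(panel["metric"]):
        values, is_g1, subjects, _ = metric_matrix(panel, metric)
        from .synthetic import ATHLETE, CONTROL
        frames.append(pd.DataFrame({
            "subject_id": subjects,
            "group": np.where(is_g1, ATHLETE, CONTROL),
            "metric": metric,
            "roi_value": values.mean(axis=1),
        }))
    return pd.concat(frames, ignore_index=True)


def single_wm_roi(panel: pd.DataFrame, alphas=(0.05, 0.01),
                  mode: str = "auto") -> pd.DataFrame:
    """Whole-white-matter summary: group comparison of per-subject ROI means."""
    roi = subject_roi_means(panel)
    from .synthetic import ATHLETE
    rows = []
    for metric, sub in roi.groupby("metric", sort=False):
        g1 = sub.loc[sub["group"] == ATHLETE, "roi_value"].to_numpy()
        g2 = sub.loc[sub["group"] != ATHLETE, "roi_value"].to_numpy()
        if g1.size < 2 or g2.size < 2:
            logger.warning("%s: a group has <2 retained subjects; skipped", metric)
            continue
        res = mann_whitney(g1, g2, mode=mode)
        row = {
            "metric": metric,
            "n1": g1.size,
            "n2": g2.size,
            "median_g1": float(np.median(g1)),
            "iqr_g1": _iqr(g1),
            "median_g2": float(np.median(g2)),
            "iqr_g2": _iqr(g2),
            "U": res.U,
            "p": res.p,
        }
        for a in alphas:
            row[f"significant_{a}"] = bool(res.p < a)
        rows.append(row)
    return pd.DataFrame(rows)
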