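"""Permutation omnibus test on the count of significant tracts.

Multiple per-tract rank-sum tests are summarized by a single statistic per
metric: T = the number of tracts significant at a fixed per-tract alpha.
Group labels are permuted uniformly over assignments that preserve the group
sizes; all per-tract U tests are recomputed for each permutation, giving the
null distribution of T.  Two summaries follow:

* an omnibus p-value for the observed count, and
* the 95th percentile of the null counts -- the largest number of significant
  tracts expected by chance alone, which bounds the plausible false-positive
  yield when no correction of the per-tract p-values is applied.

Because tract values are correlated within a subject, the null count is far
more dispersed than the Binomial(n_tracts, alpha) independence reference; the
permutation null absorbs that dependence without modelling it.

Per-tract tests inside the engine use the tie-corrected, continuity-corrected
normal approximation (the same formula :func:`tractstats.ranktests.mann_whitney`
uses in asymptotic mode), applied identically to the observed and permuted
labelings.  For a fixed seed the same permutations are reused for every metric
whose retained subject roster has the same size and order, which makes
per-metric omnibus p-values deliberately comparable (and mutually dependent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranktests import asymptotic_u_pvalue, metric_matrix, rank_sum_variance, tie_term
from scipy import stats

logger = logging.getLogger("tractstats")

DEFAULT_B = 10_000
DEFAULT_ALPHAS = (0.05, 0.01)

# p-value rules: the literal "strictly higher than" fraction, and the add-one
# >= rule that never returns exactly zero (resolution 1/(B+1)).
RULE_STRICT = "strict_greater"
RULE_GE_PLUS_ONE = "ge_plus_one"
DEFAULT_RULE = RULE_GE_PLUS_ONE


def count_significant(p_values, alpha: float) -> int:
    """Number of p-values strictly below alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        warnings.warn("count_significant called with an empty p-value list")
        return 0
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return int(np.sum(p < alpha))


def _column_tie_terms(values: np.ndarray) -> np.ndarray:
    return np.array([tie_term(values[:, j]) for j in range(values.shape[1])])


def permutation_pvalue_matrix(
    values: np.ndarray,
    is_group1: np.ndarray,
    B: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted per-tract asymptotic p-values.

    ``values`` is the subjects-by-tracts matrix, ``is_group1`` the observed
    membership.  Returns ``(p_obs, p_null)`` with shapes (T,) and (B, T).
    Ranks are computed once per tract; each permutation only re-selects which
    rows contribute to the group-1 rank sum.
    """
    values = np.asarray(values, dtype=float)
    is_group1 = np.asarray(is_group1, dtype=bool)
    n, T = values.shape
    n1 = int(is_group1.sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2 or B < 1:
        raise ValueError("need >=2 subjects per group and B >= 1")

    ranks = stats.rankdata(values, axis=0)
    ties = _column_tie_terms(values)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = np.array([rank_sum_variance(n1, n2, t) for t in ties])
    sd = np.sqrt(np.maximum(var, 0.0))

    def pvals(membership: np.ndarray) -> np.ndarray:
        w1 = membership @ ranks           # group-1 rank sums, (..., T)
        u = w1 - offset
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / sd
        p = np.minimum(1.0, 2.0 * stats.norm.sf(z))
        p[..., var <= 0] = 1.0
        return p

    p_obs = pvals(is_group1.astype(float))

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((B, n)), axis=1)
    membership = np.zeros((B, n))
    np.put_along_axis(membership, order[:, :n1], 1.0, axis=1)
    p_null = pvals(membership)
    return p_obs, p_null


def null_count_distribution(
    panel: pd.DataFrame,
    metric: str,
    alpha: float,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the significant-tract count for one metric."""
    values, is_g1, _, _ = metric_matrix(panel, metric)
    _, p_null = permutation_pvalue_matrix(values, is_g1, B, seed)
    return (p_null < alpha).sum(axis=1)


def omnibus_p(T_obs: int, null_counts, rule: str = DEFAULT_RULE) -> float:
    """Omnibus p-value of the observed count against the permutation null.

    ``strict_greater``: fraction of null counts strictly above T_obs (can be
    exactly 0).  ``ge_plus_one``: (1 + #{null >= T_obs}) / (B + 1), a valid
    Monte-Carlo p bounded below by 1/(B+1).
    """
    counts = np.asarray(null_counts)
    if counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    if rule == RULE_STRICT:
        return float(np.mean(counts > T_obs))
    if rule == RULE_GE_PLUS_ONE:
        return float((1 + np.sum(counts >= T_obs)) / (counts.size + 1))
    raise ValueError(f"unknown p-value rule {rule!r}")


def null_q95(null_counts) -> int:
    """Smallest integer q with at least 95% of null counts <= q."""
    counts = np.asarray(null_counts)
    if counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    return int(np.quantile(counts, 0.95, method="inverted_cdf"))


@dataclass
class OmnibusResult:
    metric: str
    alpha: float
    T_obs: int
    B: int
    p_perm: float
    q95_null: int
    rule: str
    seed: int
    flagged: bool              # T_obs > q95_null and p_perm < 0.05
    null_counts: np.ndarray = field(repr=False)


def run_omnibus(
    panel: pd.DataFrame,
    alphas=DEFAULT_ALPHAS,
    B: int = DEFAULT_B,
    seed: int = 0,
    rule: str = DEFAULT_RULE,
    metrics=None,
) -> list[OmnibusResult]:
    """Omnibus analysis for every metric x alpha.

    A metric/alpha cell is flagged as exceeding its null when the observed
    count is above the null 95th percentile *and* the omnibus p is below 0.05.
    The permutation p-matrix is computed once per metric and shared across
    alpha levels.
    """
    if B < 1000:
        logger.warning("B=%d gives omnibus p resolution of only %.3g", B, 1.0 / B)
    available = list(pd.unique(panel["metric"]))
    wanted = list(metrics) if metrics is not None else available
    results: list[OmnibusResult] = []
    for metric in wanted:
        if metric not in available:
            logger.warning("omnibus: metric %r absent from panel; skipped", metric)
            continue
        values, is_g1, _, _ = metric_matrix(panel, metric)
        p_obs, p_null = permutation_pvalue_matrix(values, is_g1, B, seed)
        for alpha in alphas:
            T_obs = count_significant(p_obs, alpha)
            counts = (p_null < alpha).sum(axis=1)
            p_perm = omnibus_p(T_obs, counts, rule)
            q95 = null_q95(counts)
            results.append(OmnibusResult(
                metric=metric, alpha=alpha, T_obs=T_obs, B=B, p_perm=p_perm,
                q95_null=q95, rule=rule, seed=seed,
                flagged=bool(T_obs > q95 and p_perm < 0.05),
                null_counts=counts,
            ))
    return results


def omnibus_table(results: list[OmnibusResult]) -> pd.DataFrame:
    """Tabular view of omnibus results (one row per metric x alpha)."""
    return pd.DataFrame([
        {
            "metric": r.metric, "alpha": r.alpha, "T_obs": r.T_obs,
            "p_perm": r.p_perm, "q95_null": r.q95_null, "B": r.B,
            "rule": r.rule, "flagged": r.flagged,
        }
        for r in results
    ])
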