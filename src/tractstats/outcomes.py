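"""Outcome correlations and norm-based deficit classification.

Spearman rank correlations link the global (single-WM-ROI) diffusion metrics
to clinical outcomes: CSF biomarkers (NfL, GFAP), cognitive raw scores, and
self-report symptom scales.  Correlations are computed within the injured
group only by default, since the outcome measures are either athlete-specific
(CSF was sampled in athletes only) or interpreted relative to injury.

Cognitive raw scores are converted to standard Z-scores against published
norms, z = (raw - norm_mean) / norm_sd, sign-flipped for inventories where a
higher raw score is worse, so a negative z always means worse-than-norm.  A
deficit is z <= -1.5 (boundary inclusive), i.e. performance at least 1.5 SD
below the normative mean -- about the lowest 6.7% of a normal population.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ranktests import midranks, subject_roi_means

logger = logging.getLogger("tractstats")

DEFICIT_Z_CUTOFF = -1.5
EXACT_SPEARMAN_MAX_N = 8


def normal_lower_tail(z: float) -> float:
    """Standard normal CDF at z: the population fraction at or below z SDs."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(stats.norm.cdf(z))


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y, mode: str = "auto",
             exact_threshold: int = EXACT_SPEARMAN_MAX_N) -> tuple[float, float]:
    """Spearman correlation with two-sided p.

    r_s is the Pearson correlation of midranks after pairwise deletion of
    missing values.  The p-value uses the t-transform with n - 2 df, or exact
    enumeration over all n! orderings when n <= exact_threshold (``auto``) or
    ``mode="exact"`` is forced.  Zero rank variance in either variable yields
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D samples")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("zero rank variance: Spearman correlation undefined")
        return float("nan"), float("nan")
    rx, ry = midranks(x), midranks(y)
    r = _spearman_r(rx, ry)

    use_exact = mode == "exact" or (mode == "auto" and n <= exact_threshold)
    if use_exact:
        # Permutation distribution of r over all orderings of one variable.
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_r(rx, np.asarray(perm))) >= abs(r) - 1e-12:
                count += 1
        return r, count / total
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, min(1.0, p)


def zscore_battery(
    raws: pd.DataFrame,
    norms: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Norm-based Z-scores and deficit flags for a cognitive battery.

    ``raws`` must carry ``subject_id`` plus one column per test; ``norms``
    maps test -> (norm_mean, norm_sd, higher_is_better).  Returns
    ``(flags, prevalence)``: per-(subject, test) rows with z and the deficit
    flag (z <= -1.5, boundary inclusive), and a prevalence table with the
    per-test deficit fraction plus one ``any_deficit`` row -- the fraction of
    subjects with at least one deficit among those with any scored test.
    """
    if "subject_id" not in raws.columns:
        raise ValueError("raws must carry a subject_id column")
    norm_idx = norms.set_index("test")
    rows = []
    tests = [c for c in raws.columns if c != "subject_id"]
    for test in tests:
        if test not in norm_idx.index:
            logger.warning("no norms for test %r; skipped", test)
            continue
        mean = float(norm_idx.loc[test, "norm_mean"])
        sd = float(norm_idx.loc[test, "norm_sd"])
        if sd <= 0:
            raise ValueError(f"norm_sd must be > 0 for test {test!r}")
        higher_better = bool(norm_idx.loc[test].get("higher_is_better", True))
        z = (raws[test].to_numpy(dtype=float) - mean) / sd
        if not higher_better:
            z = -z
        for sid, zi in zip(raws["subject_id"], z):
            if not np.isfinite(zi):
                continue
            rows.append({
                "subject_id": sid, "test": test, "z": float(zi),
                "deficit": bool(zi <= DEFICIT_Z_CUTOFF),
            })
    flags = pd.DataFrame(rows, columns=["subject_id", "test", "z", "deficit"])

    prev_rows = []
    if not flags.empty:
        for test, sub in flags.groupby("test", sort=False):
            prev_rows.append({"test": test, "n": len(sub),
                              "deficit_fraction": float(sub["deficit"].mean())})
        per_subject = flags.groupby("subject_id")["deficit"].any()
        prev_rows.append({"test": "any_deficit", "n": len(per_subject),
                          "deficit_fraction": float(per_subject.mean())})
    prevalence = pd.DataFrame(prev_rows, columns=["test", "n", "deficit_fraction"])
    return flags, prevalence


def correlation_table(
    panel: pd.DataFrame,
    profiles: pd.DataFrame,
    outcomes: list[str] | None = None,
    athletes_only: bool = True,
) -> pd.DataFrame:
    """Grid of Spearman correlations: single-WM-ROI metrics x outcomes.

    Pairwise deletion per cell (each cell reports its own n); cells with
    fewer than 3 complete pairs are reported with NaN r/p.  Set
    ``athletes_only=False`` for exploratory all-subject correlations.
    """
    from .synthetic import ATHLETE
    roi = subject_roi_means(panel)
    prof = profiles
    if athletes_only:
        prof = prof[prof["group"] == ATHLETE]
    if outcomes is None:
        exclude = {"subject_id", "group", "latent_injury"}
        outcomes = [c for c in prof.columns
                    if c not in exclude and pd.api.types.is_numeric_dtype(prof[c])]
    prof = prof.set_index("subject_id")

    rows = []
    for metric, sub in roi.groupby("metric", sort=False):
        if athletes_only:
            sub = sub[sub["group"] == ATHLETE]
        sub = sub.set_index("subject_id")["roi_value"]
        for outcome in outcomes:
            common = sub.index.intersection(prof.index)
            x = sub.loc[common].to_numpy(dtype=float)
            y = prof.loc[common, outcome].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            n = int(keep.sum())
            if n < 3:
                rows.append({"metric": metric, "outcome": outcome,
                             "r_s": float("nan"), "p": float("nan"), "n": n})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = spearman(x[keep], y[keep], mode="asymptotic"
                                if n > EXACT_SPEARMAN_MAX_N else "auto")
            rows.append({"metric": metric, "outcome": outcome,
                         "r_s": r, "p": p, "n": n})
    return pd.DataFrame(rows)
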