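"""End-to-end orchestration and report assembly.

Runs (optionally) the cohort generator, then the per-tract comparisons, the
single-WM-ROI summary, the permutation omnibus, the effect-size map, and the
outcome correlations, and writes every result as a tab-separated table plus a
machine-readable run summary and a manifest (config + seed + version) from
which the numeric outputs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (ALL_METRICS, DKI_METRICS, DTI_METRICS, SimulationConfig,
                        default_norms, generate_cohort, read_cohort, read_norms,
                        write_cohort)
from .ranktests import compare_tracts, single_wm_roi
from .omnibus import DEFAULT_ALPHAS, DEFAULT_B, DEFAULT_RULE, omnibus_table, run_omnibus
from .effects import effect_map
from .outcomes import correlation_table, zscore_battery

logger = logging.getLogger("tractstats")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_significance(
    per_metric_counts: dict[str, int],
    n_tracts: int = 72,
) -> dict:
    """Fractions of significant per-tract comparisons by modality.

    ``per_metric_counts`` maps metric names (any subset of the 4 DTI and
    7 DKI metrics) to significant-tract counts.  Fractions use
    n_tracts x (number of metrics provided) denominators per family and
    overall; percentages are integer-rounded (half away from zero), raw
    fractions are retained.
    """
    unknown = sorted(set(per_metric_counts) - set(ALL_METRICS))
    if unknown:
        raise ValueError(f"unknown metric keys: {unknown}")
    for m, c in per_metric_counts.items():
        if not (0 <= c <= n_tracts):
            raise ValueError(f"count for {m} out of range [0, {n_tracts}]")

    def family(metrics):
        present = [m for m in metrics if m in per_metric_counts]
        total = sum(per_metric_counts[m] for m in present)
        denom = n_tracts * len(present)
        return total, denom, (total / denom if denom else float("nan"))

    dti_n, dti_d, dti_f = family(DTI_METRICS)
    dki_n, dki_d, dki_f = family(DKI_METRICS)
    all_n, all_d, all_f = family(ALL_METRICS)
    return {
        "dti_count": dti_n, "dti_comparisons": dti_d, "dti_fraction": dti_f,
        "dti_percent": round_half_away(100 * dti_f) if dti_d else None,
        "dki_count": dki_n, "dki_comparisons": dki_d, "dki_fraction": dki_f,
        "dki_percent": round_half_away(100 * dki_f) if dki_d else None,
        "total_count": all_n, "total_comparisons": all_d, "total_fraction": all_f,
        "total_percent": round_half_away(100 * all_f) if all_d else None,
    }


@dataclass
class RunConfig:
    """Analysis run description: inputs (or a simulation), knobs, outputs."""
    input_dir: str | None = None         # cohort tables to analyze
    simulation: SimulationConfig | None = None  # or simulate in-process
    norms_path: str | None = None
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    B: int = DEFAULT_B
    seed: int = 0
    bound_method: str = "normal"
    p_rule: str = DEFAULT_RULE
    mw_mode: str = "auto"
    out_dir: str = "tractstats_run"


@dataclass
class ResultBundle:
    panel: pd.DataFrame
    profiles: pd.DataFrame
    tract_stats: pd.DataFrame
    single_roi: pd.DataFrame
    omnibus: pd.DataFrame
    effects: pd.DataFrame
    effects_summary: pd.DataFrame
    correlations: pd.DataFrame
    deficits: pd.DataFrame = field(default_factory=pd.DataFrame)
    deficit_prevalence: pd.DataFrame = field(default_factory=pd.DataFrame)
    summary: dict = field(default_factory=dict)
    out_dir: Path | None = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis and write all outputs under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress\n")

    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            panel, profiles = generate_cohort(config.simulation)
            write_cohort(panel, profiles, out, norms=default_norms())
            norms = default_norms()
        elif config.input_dir is not None:
            panel, profiles = read_cohort(config.input_dir)
            norms = read_norms(config.norms_path) if config.norms_path else None
        else:
            raise ValueError("RunConfig needs input_dir or simulation")

        stage = "tract_stats"
        tract_stats = compare_tracts(panel, alphas=config.alphas, mode=config.mw_mode)
        _write_tsv(tract_stats, out / "tract_stats.tsv")
        single_roi = single_wm_roi(panel, alphas=config.alphas, mode=config.mw_mode)
        _write_tsv(single_roi, out / "single_roi.tsv")

        stage = "permutation_omnibus"
        results = run_omnibus(panel, alphas=config.alphas, B=config.B,
                              seed=config.seed, rule=config.p_rule)
        omnibus = omnibus_table(results)
        _write_tsv(omnibus, out / "omnibus.tsv")

        stage = "effect_sizes"
        effects, effects_summary = effect_map(
            panel, alpha=0.05, method=config.bound_method, seed=config.seed)
        _write_tsv(effects, out / "effects.tsv")
        _write_tsv(effects_summary, out / "effects_summary.tsv")

        stage = "correlations"
        correlations = correlation_table(panel, profiles)
        _write_tsv(correlations, out / "correlations.tsv")
        deficits = pd.DataFrame()
        prevalence = pd.DataFrame()
        if norms is not None:
            scored = [t for t in norms["test"] if t in profiles.columns]
            if scored:
                deficits, prevalence = zscore_battery(
                    profiles[["subject_id"] + scored], norms)
                _write_tsv(deficits, out / "deficits.tsv")
                _write_tsv(prevalence, out / "deficit_prevalence.tsv")

        stage = "report"
        summary = _build_summary(config, tract_stats, omnibus)
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        (out / "manifest.yaml").write_text(_manifest_yaml(config))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc

    incomplete.unlink(missing_ok=True)
    return ResultBundle(
        panel=panel, profiles=profiles, tract_stats=tract_stats,
        single_roi=single_roi, omnibus=omnibus, effects=effects,
        effects_summary=effects_summary, correlations=correlations,
        deficits=deficits, deficit_prevalence=prevalence,
        summary=summary, out_dir=out,
    )


def _build_summary(config: RunConfig, tract_stats: pd.DataFrame,
                   omnibus: pd.DataFrame) -> dict:
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "B": config.B,
        "alphas": list(config.alphas),
        "p_rule": config.p_rule,
        "bound_method": config.bound_method,
    }
    n_tracts = int(tract_stats.groupby("metric")["tract_id"].nunique().max()) \
        if not tract_stats.empty else 0
    summary["n_tracts"] = n_tracts
    for alpha in config.alphas:
        col = f"significant_{alpha}"
        counts = {m: int(sub[col].sum())
                  for m, sub in tract_stats.groupby("metric", sort=False)}
        entry: dict = {"per_metric_counts": counts}
        known = {m: c for m, c in counts.items() if m in ALL_METRICS}
        if known and n_tracts:
            entry["fractions"] = summarize_significance(known, n_tracts=n_tracts)
        sub = omnibus[omnibus["alpha"] == alpha]
        entry["flagged_metrics"] = sub.loc[sub["flagged"], "metric"].tolist()
        summary[f"alpha_{alpha}"] = entry
    return summary


def _manifest_yaml(config: RunConfig) -> str:
    cfg = dataclasses.asdict(config)
    if cfg.get("simulation") is not None:
        sim = cfg["simulation"]
        for key, val in list(sim.items()):
            if isinstance(val, tuple):
                sim[key] = list(val)
            elif isinstance(val, dict):
                sim[key] = {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in val.items()}
    cfg["alphas"] = list(cfg["alphas"])
    cfg["version"] = __version__
    return yaml.safe_dump(cfg, sort_keys=False)
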