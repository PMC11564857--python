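"""Synthetic two-group tractometry cohorts.

Generates cohorts of per-subject, per-tract diffusion-metric means (the layout
produced downstream of TractSeg-style tractometry: 72 white-matter tracts for
up to 11 DTI/DKI metrics) together with subject profiles carrying symptom
scores, neuropsychological raw scores, and CSF biomarkers (NfL, GFAP).

Generative model
----------------
A single latent injury factor L drives everything that differs between groups:

* athletes:  L ~ |N(1, 0.25)|   (variance 0.25, i.e. SD 0.5)
* controls:  L = 0

For metric k with baseline center c_k and scale s_k, subject i, tract t:

    value[i, t] = c_k + sign_k * delta_k * L_i * s_k * 1[t in affected_k]
                  + s_k * eps[i, t]

with eps multivariate normal across tracts under equicorrelation rho and unit
variance.  Fractional-anisotropy metrics are clipped to [0, 1].

CSF NfL increases with L (NfL = base + coupling * L + noise, floored at 0);
GFAP is independent of L.  Cognitive raw scores decrease with L (or increase
where a higher raw score is worse, per the norms table flag).  Missingness is
applied by dropping whole subjects per modality, mirroring how real tractometry
cohorts lose subjects to artefacts or incomplete protocols.

Default calibration: baseline centers/scales are the healthy-control
single-WM-ROI medians with scale = IQR/1.349 (normal-theory conversion);
effect templates are concussion-like, kurtosis-dominant alterations
(DKI FA and AK increased, DKI RD and RK decreased, diffusivities mildly
decreased in the injured group).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tractstats")

# ---------------------------------------------------------------------------
# Metric vocabulary and fixed study structure
# ---------------------------------------------------------------------------

DTI_METRICS: tuple[str, ...] = ("DTI_FA", "DTI_MD", "DTI_AD", "DTI_RD")
DKI_METRICS: tuple[str, ...] = (
    "DKI_FA", "DKI_MD", "DKI_AD", "DKI_RD", "DKI_MK", "DKI_AK", "DKI_RK",
)
ALL_METRICS: tuple[str, ...] = DTI_METRICS + DKI_METRICS
FA_METRICS: tuple[str, ...] = ("DTI_FA", "DKI_FA")

N_TRACTS_DEFAULT = 72

ATHLETE = "athlete"
CONTROL = "control"
GROUPS = (ATHLETE, CONTROL)

# SCAT5 symptom inventory: 22 symptoms rated 0-6 each.
SCAT5_N_ITEMS = 22
SCAT5_MAX_ITEM_RATING = 6
SCAT5_MAX_SEVERITY = SCAT5_N_ITEMS * SCAT5_MAX_ITEM_RATING  # 132

# Healthy-control single-WM-ROI (median, IQR) per metric.  Diffusivities in
# 1e-3 mm^2/s, FA and kurtosis metrics dimensionless.
CONTROL_BASELINES: dict[str, tuple[float, float]] = {
    "DTI_FA": (0.412, 0.023),
    "DTI_MD": (0.779, 0.026),
    "DTI_AD": (1.140, 0.032),
    "DTI_RD": (0.600, 0.034),
    "DKI_FA": (0.438, 0.013),
    "DKI_MD": (0.948, 0.024),
    "DKI_AD": (1.413, 0.046),
    "DKI_RD": (0.710, 0.028),
    "DKI_MK": (0.966, 0.072),
    "DKI_AK": (0.842, 0.033),
    "DKI_RK": (1.185, 0.129),
}

# IQR -> SD under normality.
IQR_TO_SD = 1.349

# Concussion-like effect template: (n affected tracts, standardized shift per
# latent unit, direction in athletes).  Kurtosis-derived metrics carry the
# dominant alterations; plain-DTI diffusivities shift mildly; DTI FA and DKI AD
# are left unaffected.
DEFAULT_EFFECTS: dict[str, tuple[int, float, int]] = {
    "DTI_FA": (0, 0.0, +1),
    "DTI_MD": (18, 1.0, -1),
    "DTI_AD": (14, 1.0, -1),
    "DTI_RD": (12, 1.0, -1),
    "DKI_FA": (52, 3.1, +1),
    "DKI_MD": (19, 1.7, -1),
    "DKI_AD": (0, 0.0, +1),
    "DKI_RD": (36, 1.15, -1),
    "DKI_MK": (6, 0.8, -1),
    "DKI_AK": (35, 1.6, +1),
    "DKI_RK": (29, 1.65, -1),
}

# Cognitive battery: test -> (norm mean, norm SD, higher raw is better,
# standardized decline per latent unit in the injured group).
NEUROPSYCH_BATTERY: dict[str, tuple[float, float, bool, float]] = {
    "RBANS_total": (100.0, 15.0, True, 1.3),
    "SDMT": (55.0, 10.0, True, 0.9),
    "d2": (450.0, 85.0, True, 1.5),
    "WAIS_digit_span": (26.0, 5.5, True, 0.3),
    "BRIEF_GEC": (100.0, 25.0, False, 1.0),
}

PANEL_COLUMNS = ("subject_id", "group", "metric", "tract_id", "value")


def default_norms() -> pd.DataFrame:
    """Normative table for the cognitive battery (test, mean, SD, direction)."""
    rows = [
        {"test": t, "norm_mean": m, "norm_sd": s, "higher_is_better": hib}
        for t, (m, s, hib, _) in NEUROPSYCH_BATTERY.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_centers() -> dict[str, float]:
    return {m: c for m, (c, _) in CONTROL_BASELINES.items()}


def _default_scales() -> dict[str, float]:
    return {m: iqr / IQR_TO_SD for m, (_, iqr) in CONTROL_BASELINES.items()}


def _default_affected(n_tracts: int = N_TRACTS_DEFAULT) -> dict[str, tuple[int, ...]]:
    return {m: tuple(range(min(k, n_tracts))) for m, (k, _, _) in DEFAULT_EFFECTS.items()}


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    Group 1 is the injured (athlete) group, group 2 the control group.
    ``missing_rate`` holds per-modality whole-subject dropout fractions for the
    keys ``DTI``, ``DKI``, ``neuropsych`` and ``CSF``; the CSF rate is the
    fraction of athletes without a lumbar puncture (controls carry no CSF).
    """

    n_group1: int = 22
    n_group2: int = 22
    n_tracts: int = N_TRACTS_DEFAULT
    metrics: tuple[str, ...] = ALL_METRICS
    baseline_center: dict[str, float] = field(default_factory=_default_centers)
    baseline_scale: dict[str, float] = field(default_factory=_default_scales)
    inter_tract_rho: float = 0.5
    affected_tracts: dict[str, tuple[int, ...]] = field(default_factory=_default_affected)
    effect_delta: dict[str, float] = field(
        default_factory=lambda: {m: d for m, (_, d, _) in DEFAULT_EFFECTS.items()})
    effect_sign: dict[str, int] = field(
        default_factory=lambda: {m: s for m, (_, _, s) in DEFAULT_EFFECTS.items()})
    biomarker_coupling: float = 70.0       # ng/L per latent unit
    nfl_base: float = 150.0                # ng/L
    nfl_noise_sd: float = 25.0             # ng/L
    gfap_base: float = 248.0               # ng/L
    gfap_noise_sd: float = 78.0            # ng/L
    missing_rate: dict[str, float] = field(default_factory=lambda: {
        "DTI": 0.07, "DKI": 0.11, "neuropsych": 0.11, "CSF": 0.27})
    seed: int = 0

    def validate(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("both groups need at least 2 subjects")
        if not (0.0 <= self.inter_tract_rho < 1.0):
            raise ValueError(
                f"inter_tract_rho must be in [0, 1); got {self.inter_tract_rho}"
                " (rho >= 1 implies a non-positive-definite tract correlation)")
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be positive")
        if len(self.metrics) == 0:
            raise ValueError("metric list must not be empty")
        for m in self.metrics:
            if m not in self.baseline_center or m not in self.baseline_scale:
                raise ValueError(f"metric {m!r} lacks a baseline center/scale")
            if self.baseline_scale[m] <= 0:
                raise ValueError(f"baseline_scale[{m!r}] must be > 0")
            for t in self.affected_tracts.get(m, ()):
                if not (0 <= t < self.n_tracts):
                    raise ValueError(
                        f"affected tract index {t} for {m!r} out of range "
                        f"[0, {self.n_tracts})")
        for mod, rate in self.missing_rate.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing_rate[{mod!r}] must be in [0, 1)")

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A no-effect configuration: both groups drawn from one distribution."""
        cfg = cls(
            effect_delta={m: 0.0 for m in ALL_METRICS},
            biomarker_coupling=0.0,
            missing_rate={"DTI": 0.0, "DKI": 0.0, "neuropsych": 0.0, "CSF": 0.0},
        )
        return dataclasses.replace(cfg, **overrides)

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _modality(metric: str) -> str:
    return metric.split("_", 1)[0]


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns ``(panel, profiles)``.

    ``panel`` is the long-format tract-metric table with columns
    ``subject_id, group, metric, tract_id, value``; ``profiles`` has one row
    per subject with symptom scores, cognitive raws, and CSF biomarkers.
    The ``latent_injury`` column in ``profiles`` is simulation ground truth
    and is never consumed by the analysis stages.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n1, n2 = config.n_group1, config.n_group2
    n = n1 + n2
    groups = np.array([ATHLETE] * n1 + [CONTROL] * n2)
    subject_ids = np.array(
        [f"src{i + 1:03d}" for i in range(n1)]
        + [f"ctl{i + 1:03d}" for i in range(n2)])

    latent = np.zeros(n)
    latent[:n1] = np.abs(rng.normal(1.0, 0.5, size=n1))

    # Whole-subject missingness per modality (same draw governs every metric
    # of the modality, mirroring per-protocol subject exclusion).
    modalities = sorted({_modality(m) for m in config.metrics})
    missing: dict[str, np.ndarray] = {}
    for mod in modalities:
        rate = config.missing_rate.get(mod, 0.0)
        missing[mod] = rng.random(n) < rate

    rho = config.inter_tract_rho
    T = config.n_tracts
    frames = []
    for metric in config.metrics:
        center = config.baseline_center[metric]
        scale = config.baseline_scale[metric]
        delta = config.effect_delta.get(metric, 0.0)
        sign = config.effect_sign.get(metric, +1)
        affected = np.asarray(config.affected_tracts.get(metric, ()), dtype=int)

        # Equicorrelated noise: shared subject factor + tract-specific part.
        shared = rng.standard_normal(n)
        eps = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * rng.standard_normal((n, T))

        values = center + scale * eps
        if delta != 0.0 and affected.size:
            shift = np.zeros(T)
            shift[affected] = sign * delta * scale
            values = values + latent[:, None] * shift[None, :]
        if metric in FA_METRICS:
            values = np.clip(values, 0.0, 1.0)

        keep = ~missing[_modality(metric)]
        if keep.sum() == 0:
            continue
        idx = np.flatnonzero(keep)
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(subject_ids[idx], T),
            "group": np.repeat(groups[idx], T),
            "metric": metric,
            "tract_id": np.tile(np.arange(T), idx.size),
            "value": values[idx].ravel(),
        }))
    panel = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(PANEL_COLUMNS))

    profiles = _generate_profiles(config, rng, subject_ids, groups, latent)
    return panel, profiles


def _generate_profiles(
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_ids: np.ndarray,
    groups: np.ndarray,
    latent: np.ndarray,
) -> pd.DataFrame:
    n = subject_ids.size
    is_ath = groups == ATHLETE

    # SCAT5: symptomatic athletes; controls report no concussion symptoms.
    severity = np.zeros(n)
    nsymptoms = np.zeros(n)
    severity[is_ath] = 64.0 + 25.0 * (latent[is_ath] - 1.0) + rng.normal(0, 10, is_ath.sum())
    nsymptoms[is_ath] = 20.0 + 2.0 * (latent[is_ath] - 1.0) + rng.normal(0, 1.5, is_ath.sum())
    severity = np.clip(np.rint(severity), 0, SCAT5_MAX_SEVERITY).astype(int)
    nsymptoms = np.clip(np.rint(nsymptoms), 0, SCAT5_N_ITEMS).astype(int)

    prof = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "SCAT5_severity": severity,
        "SCAT5_nsymptoms": nsymptoms,
    })

    # Cognitive battery: person-level ability z, shifted down by the latent
    # factor (or up for inventories where a higher raw score is worse).
    np_missing = rng.random(n) < config.missing_rate.get("neuropsych", 0.0)
    for test, (mean, sd, higher_better, eff) in NEUROPSYCH_BATTERY.items():
        z0 = rng.standard_normal(n)
        z = z0 - eff * latent if higher_better else z0 + eff * latent
        raw = mean + sd * z
        raw[np_missing] = np.nan
        prof[test] = raw

    # Self-report symptom scales (higher = worse except LiSat-style not modelled).
    mfs = 4.5 + 16.0 * latent + rng.normal(0, 4, n)
    hads_a = 3.0 + 6.0 * latent + rng.normal(0, 2, n)
    hads_d = 1.0 + 5.0 * latent + rng.normal(0, 2, n)
    for name, vals in (("MFS", mfs), ("HADS_A", hads_a), ("HADS_D", hads_d)):
        v = np.clip(vals, 0, None)
        v[np_missing] = np.nan
        prof[name] = v

    # CSF biomarkers: athletes only (controls are not sampled).
    nfl = config.nfl_base + config.biomarker_coupling * latent + rng.normal(
        0, config.nfl_noise_sd, n)
    gfap = config.gfap_base + rng.normal(0, config.gfap_noise_sd, n)
    csf_missing = (~is_ath) | (rng.random(n) < config.missing_rate.get("CSF", 0.0))
    nfl = np.clip(nfl, 0, None)
    gfap = np.clip(gfap, 0, None)
    nfl[csf_missing] = np.nan
    gfap[csf_missing] = np.nan
    prof["NfL"] = nfl
    prof["GFAP"] = gfap

    prof["latent_injury"] = latent
    return prof


# ---------------------------------------------------------------------------
# Cohort I/O (plain CSV, round-trip exact in decimal text)
# ---------------------------------------------------------------------------

PANEL_FILE = "tract_metrics.csv"
PROFILE_FILE = "profiles.csv"
NORMS_FILE = "norms.csv"


def write_cohort(
    panel: pd.DataFrame,
    profiles: pd.DataFrame,
    directory: str | Path,
    norms: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the cohort tables as CSV; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    p = directory / PANEL_FILE
    panel.to_csv(p, index=False)
    paths.append(p)
    p = directory / PROFILE_FILE
    profiles.to_csv(p, index=False)
    paths.append(p)
    if norms is not None:
        p = directory / NORMS_FILE
        norms.to_csv(p, index=False)
        paths.append(p)
    return paths


def validate_panel(panel: pd.DataFrame) -> None:
    """Reject malformed panels, naming offending rows (1-based data rows)."""
    missing_cols = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing_cols:
        raise ValueError(f"panel is missing columns: {missing_cols}")
    bad_group = ~panel["group"].isin(GROUPS)
    if bad_group.any():
        rows = (np.flatnonzero(bad_group.to_numpy()) + 1)[:5].tolist()
        labels = sorted(panel.loc[bad_group, "group"].unique().tolist())
        raise ValueError(f"unknown group labels {labels} at data rows {rows}")
    values = panel["value"].to_numpy(dtype=float)
    nonfinite = ~np.isfinite(values)
    if nonfinite.any():
        rows = (np.flatnonzero(nonfinite) + 1)[:5].tolist()
        raise ValueError(f"non-finite metric values at data rows {rows}")
    dup = panel.duplicated(subset=["subject_id", "metric", "tract_id"], keep=False)
    if dup.any():
        first = panel.loc[dup].iloc[0]
        rows = (np.flatnonzero(dup.to_numpy()) + 1)[:5].tolist()
        raise ValueError(
            "duplicate (subject, metric, tract) key "
            f"({first['subject_id']}, {first['metric']}, {first['tract_id']}) "
            f"at data rows {rows}")


def read_cohort(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`, validating the panel."""
    directory = Path(directory)
    panel = pd.read_csv(directory / PANEL_FILE)
    validate_panel(panel)
    profiles = pd.read_csv(directory / PROFILE_FILE)
    if "subject_id" not in profiles.columns or "group" not in profiles.columns:
        raise ValueError("profiles table must carry subject_id and group columns")
    bad = ~profiles["group"].isin(GROUPS)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1)[:5].tolist()
        raise ValueError(f"profiles: unknown group labels at data rows {rows}")
    return panel, profiles


def read_norms(path: str | Path) -> pd.DataFrame:
    norms = pd.read_csv(path)
    required = {"test", "norm_mean", "norm_sd"}
    if not required.issubset(norms.columns):
        raise ValueError(f"norms table must carry columns {sorted(required)}")
    if "higher_is_better" not in norms.columns:
        norms["higher_is_better"] = True
    if (norms["norm_sd"] <= 0).any():
        raise ValueError("norm_sd must be > 0 for every test")
    return norms


def read_tractseg_subject(
    path: str | Path, subject_id: str, group: str
) -> pd.DataFrame:
    """Read one subject's tractometry matrix (rows = metrics, one column per
    tract) into the long panel layout."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    wide = pd.read_csv(path, index_col=0)
    long = wide.stack().reset_index()
    long.columns = ["metric", "tract_id", "value"]
    long.insert(0, "group", group)
    long.insert(0, "subject_id", subject_id)
    try:
        long["tract_id"] = long["tract_id"].astype(int)
    except (TypeError, ValueError):
        pass  # named tracts are allowed
    return long[list(PANEL_COLUMNS)]


def write_tractseg_subject(panel: pd.DataFrame, subject_id: str, path: str | Path) -> Path:
    """Write one subject's slice of a panel in the wide per-subject layout."""
    sub = panel[panel["subject_id"] == subject_id]
    if sub.empty:
        raise ValueError(f"subject {subject_id!r} not present in panel")
    wide = sub.pivot(index="metric", columns="tract_id", values="value")
    path = Path(path)
    wide.to_csv(path)
    return path
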