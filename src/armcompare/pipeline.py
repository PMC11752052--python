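"""Full comparability analysis: baseline-characteristic meta-analyses,
arm-type SMD simulation with sensitivity variants, trial-sites
comparison, and the active-vs-control intensity battery, with report
writers producing deterministic CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .correlation_sim import (
    SimulationSpec,
    SimulationSummary,
    run_simulation,
)
from .effect_size import baseline_fractions, compute_effects
from .errors import ArmCompareError, CoverageError, DomainError
from .meta_core import (
    MetaResult,
    RandomEffectsMeta,
    SubgroupComparison,
    TwoSampleComparison,
    cohens_d_pooled,
    subgroup_difference,
    welch_t,
)
from .multilevel import arm_type_contrast, fit_multilevel, rtm_adjusted_fit
from .trial_data import (
    REFERENCE_R,
    FilterSpec,
    TrialDatabase,
    apply_filter,
    load_trials,
)

logger = logging.getLogger("armcompare")

INTENSITY_VARS = (
    "n_sessions", "sessions_per_week", "session_minutes", "total_hours",
)

#: sensitivity filters applied to the arm-type SMD analysis, by name
DEFAULT_SENSITIVITY: dict[str, dict] = {
    "exclude_waitlist": {"exclude_waitlist": True},
    "exclude_subclinical": {"exclude_subclinical": True},
    "cdrs_only": {"scale_in": ["CDRS-R"]},
    "hamd_only": {"scale_in": ["HAM-D"]},
    "variance_lt_0.02": {"max_effect_variance": 0.02},
    "post_sd_reported": {"require_post_sd": True},
}


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one full analysis run."""

    input_dir: str | None = None
    arms_path: str | None = None
    studies_path: str | None = None
    scales_path: str | None = None
    out_dir: str = "armcompare_out"
    seed: int = 0
    n_sims: int = 1000
    r_low: float = 0.45
    r_high: float = 0.9
    draw_mode: str = "per_dataset"
    threshold: float = 1.645
    alpha: float = 0.05
    bonferroni_m: int = 4
    hedges: bool = True
    standardizer: str = "baseline"
    method: str = "REML"
    sensitivity: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SENSITIVITY.items()}
    )

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.bonferroni_m

    def simulation_spec(self) -> SimulationSpec:
        return SimulationSpec(
            n_sims=self.n_sims, r_low=self.r_low, r_high=self.r_high,
            draw_mode=self.draw_mode, seed=self.seed,
            threshold=self.threshold,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ArmCompareError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    fig2_data: pd.DataFrame
    fig3_data: pd.DataFrame
    sites: dict
    stability: pd.DataFrame
    rtm: dict
    simulations: dict[str, SimulationSummary]


# ---------------------------------------------------------------------
# Table 1: baseline characteristics
# ---------------------------------------------------------------------

def _study_severity(db: TrialDatabase) -> pd.DataFrame:
    """One severity row per study: n-weighted mean arm baseline fraction
    and its SE on the fraction scale (pooled baseline SD / range / sqrt n)."""
    fr = baseline_fractions(db)
    arms = db.arms.assign(fraction=fr)
    rows = []
    for sid, grp in arms.groupby("study_id"):
        n = grp["n"].to_numpy(dtype=float)
        frac = float(np.average(grp["fraction"], weights=n))
        rngs = np.array([db.scale_of(s).range for s in grp["scale"]])
        sd_fr = grp["baseline_sd"].to_numpy(dtype=float) / rngs
        pooled_sd = float(np.sqrt(
            np.sum((n - 1) * sd_fr**2) / max(np.sum(n - 1), 1.0)
        ))
        rows.append({"study_id": sid, "value": frac,
                     "variance": pooled_sd**2 / float(n.sum())})
    return pd.DataFrame(rows)


def _study_female(db: TrialDatabase) -> pd.DataFrame:
    st = db.studies
    keep = st["percent_female"].notna() & (st["percent_female"] < 100.0)
    st = st[keep]
    pf = st["percent_female"].to_numpy(dtype=float)
    n = st["n_total"].to_numpy(dtype=float)
    prop = np.clip(pf / 100.0, np.where(n > 0, 0.5 / np.maximum(n, 1), 0.005),
                   1 - np.where(n > 0, 0.5 / np.maximum(n, 1), 0.005))
    var = np.where(
        np.isfinite(n) & (n > 0), 100.0**2 * prop * (1 - prop) / n, np.nan
    )
    common = np.nanmean(var) if np.isfinite(var).any() else np.var(pf)
    var = np.where(np.isfinite(var), var, common)
    return pd.DataFrame({"study_id": st["study_id"], "value": pf,
                         "variance": var})


def _study_age(db: TrialDatabase) -> pd.DataFrame:
    st = db.studies[db.studies["mean_age"].notna()]
    sd = st["sd_age"].to_numpy(dtype=float)
    common_sd = np.nanmean(sd) if np.isfinite(sd).any() else 1.5
    sd = np.where(np.isfinite(sd), sd, common_sd)
    n = st["n_total"].to_numpy(dtype=float)
    n = np.where(np.isfinite(n) & (n > 0), n, np.nanmedian(n))
    return pd.DataFrame({"study_id": st["study_id"],
                         "value": st["mean_age"].to_numpy(dtype=float),
                         "variance": sd**2 / n})


_CHARACTERISTICS = {
    "severity": _study_severity,
    "percent_female": _study_female,
    "age": _study_age,
}

_TABLE1_VARIANTS = {
    "overall": {},
    "excluding_subclinical": {"exclude_subclinical": True},
    "excluding_waitlist": {"exclude_waitlist": True},
}


def compare_baseline_characteristics(
    db: TrialDatabase, method: str = "REML"
) -> pd.DataFrame:
    """Per-modality random-effects meta-analyses of baseline severity
    (fraction of scale range), percent female (all-female trials
    excluded) and mean age, each overall and under the subclinical /
    waitlist exclusions, with the between-modality subgroup p."""
    rows = []
    for variant, crit in _TABLE1_VARIANTS.items():
        filtered = apply_filter(db, crit) if crit else db
        for char, extractor in _CHARACTERISTICS.items():
            per_study = extractor(filtered)
            modality = per_study["study_id"].map(
                filtered.studies.set_index("study_id")["modality"]
            )
            results: dict[str, MetaResult] = {}
            for mod in ("psychotherapy", "medication"):
                sub = per_study[modality == mod]
                if len(sub) < 2:
                    results[mod] = None
                    continue
                est = RandomEffectsMeta(method=method).fit(
                    sub["value"], sub["variance"]
                )
                results[mod] = est.result_()
            p = (
                subgroup_difference(
                    {m: r for m, r in results.items() if r is not None}
                ).p
                if all(r is not None for r in results.values())
                else np.nan
            )
            for mod, res in results.items():
                rows.append({
                    "characteristic": char, "variant": variant,
                    "subgroup": mod,
                    "K": res.k if res else 0,
                    "mean": res.pooled if res else np.nan,
                    "se": res.se if res else np.nan,
                    "ci_low": res.ci_low if res else np.nan,
                    "ci_high": res.ci_high if res else np.nan,
                    "tau2": res.tau2 if res else np.nan,
                    "p_subgroup": p,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Trial sites
# ---------------------------------------------------------------------

def compare_sites(db: TrialDatabase) -> dict:
    """Welch t on per-study site counts by modality plus multisite
    (n_sites > 1) proportions."""
    st = db.studies[db.studies["n_sites"].notna()]
    if len(st) == 0:
        raise CoverageError("no study reports a site count")
    out: dict = {"per_modality": {}, "degenerate": False}
    groups = {}
    for mod in ("medication", "psychotherapy"):
        counts = st.loc[st["modality"] == mod, "n_sites"].to_numpy(dtype=float)
        if len(counts) < 2:
            raise CoverageError(f"fewer than two {mod} studies report sites")
        multi = int((counts > 1).sum())
        out["per_modality"][mod] = {
            "k": int(len(counts)),
            "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)),
            "n_multisite": multi,
            "prop_multisite": multi / len(counts),
        }
        groups[mod] = counts
    m, p_ = out["per_modality"]["medication"], out["per_modality"]["psychotherapy"]
    try:
        cmp = welch_t(m["k"], m["mean"], m["sd"], p_["k"], p_["mean"], p_["sd"])
        out["welch"] = dataclasses.asdict(cmp)
    except DomainError:
        out["welch"] = None
        out["degenerate"] = True
    return out


# ---------------------------------------------------------------------
# Table 2: intensity of psychotherapy arms
# ---------------------------------------------------------------------

def compare_intensity(
    db: TrialDatabase,
    bonferroni_threshold: float = 0.0125,
    include_waitlist_excluded: bool = True,
) -> pd.DataFrame:
    """Active vs control comparison of psychotherapy-arm intensity
    descriptors, available-case per variable, with Welch t, pooled-SD
    Cohen's d, and significance at the Bonferroni-corrected threshold.
    """
    variants = {"overall": {}}
    if include_waitlist_excluded:
        variants["excluding_waitlist"] = {"exclude_waitlist": True}
    rows = []
    for variant, crit in variants.items():
        filtered = apply_filter(db, crit) if crit else db
        arms = filtered.arms_with_modality()
        psy = arms[arms["modality"] == "psychotherapy"]
        for var in INTENSITY_VARS:
            stats_by_role = {}
            for role in ("active", "control"):
                vals = psy.loc[psy["role"] == role, var].dropna()
                stats_by_role[role] = (
                    len(vals), float(vals.mean()) if len(vals) else np.nan,
                    float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                )
            (k1, m1, s1), (k2, m2, s2) = (
                stats_by_role["active"], stats_by_role["control"]
            )
            if k1 < 2 or k2 < 2:
                rows.append({
                    "variable": var, "variant": variant,
                    "k_active": k1, "mean_active": m1, "sd_active": s1,
                    "k_control": k2, "mean_control": m2, "sd_control": s2,
                    "d": np.nan, "d_ci_low": np.nan, "d_ci_high": np.nan,
                    "t": np.nan, "df": np.nan, "p": np.nan,
                    "significant": False, "available": False,
                })
                continue
            try:
                cmp = welch_t(k1, m1, s1, k2, m2, s2)
            except DomainError:
                cmp = None
            rows.append({
                "variable": var, "variant": variant,
                "k_active": k1, "mean_active": m1, "sd_active": s1,
                "k_control": k2, "mean_control": m2, "sd_control": s2,
                "d": cmp.d if cmp else np.nan,
                "d_ci_low": cmp.d_ci_low if cmp else np.nan,
                "d_ci_high": cmp.d_ci_high if cmp else np.nan,
                "t": cmp.t if cmp else np.nan,
                "df": cmp.df if cmp else np.nan,
                "p": cmp.p if cmp else np.nan,
                "significant": bool(cmp and cmp.p < bonferroni_threshold),
                "available": cmp is not None,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------

def _fig2_frame(summaries: Mapping[str, SimulationSummary]) -> pd.DataFrame:
    rows = []
    for analysis, summ in summaries.items():
        for t, d in sorted(summ.per_arm_type.items()):
            rows.append({
                "analysis": analysis, "arm_type": t,
                "smd": d["mean_smd"], "ci_low": d["mean_ci_low"],
                "ci_high": d["mean_ci_high"],
                "sd_across_sims": d["sd_across_sims"],
            })
    return pd.DataFrame(rows)


def _fig3_frame(db: TrialDatabase, hedges: bool, standardizer: str
                ) -> pd.DataFrame:
    eff = compute_effects(db, REFERENCE_R, hedges=hedges,
                          standardizer=standardizer)
    ctl = eff[eff["arm_type"].str.endswith("_control")].copy()
    n = db.arms.set_index(["study_id", "arm_id"])["n"]
    ctl["n"] = pd.MultiIndex.from_frame(ctl[["study_id", "arm_id"]]).map(n)
    ctl["weight"] = 1.0 / ctl["variance"]
    ctl["modality"] = ctl["arm_type"].str.replace("_control", "", regex=False)
    return ctl[["study_id", "arm_id", "modality", "n", "smd",
                "variance", "weight"]]


def run_full_analysis(
    config: AnalysisConfig,
    db: TrialDatabase | None = None,
) -> ReportBundle:
    """Execute the entire analysis and write every report section.

    Sections run in order: load, arm-type SMD simulation (overall and
    one per sensitivity filter), regression-to-the-mean adjustment,
    baseline characteristics, trial sites, intensity comparison.  A
    section failure aborts with a section-named error after the
    completed sections are flushed to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"armcompare {_pkg_version}", f"seed={config.seed}",
                 f"n_sims={config.n_sims}"]
    written: list[str] = []

    def flush_csv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, index=False, float_format="%.10g",
                  lineterminator="\n")
        written.append(name)

    def flush_json(name: str, obj) -> None:
        with open(out / name, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        written.append(name)

    def fail(section: str, exc: Exception):
        (out / "run.log").write_text("\n".join(
            log_lines + [f"FAILED in section {section}: {exc}"]) + "\n")
        raise ArmCompareError(f"section {section!r} failed: {exc}") from exc

    try:
        if db is None:
            src = config.input_dir or config.arms_path
            db = load_trials(src, config.studies_path, config.scales_path)
        log_lines.append(f"db: {db.n_studies} studies, {db.n_arms} arms")
        log_lines.append(f"report: {json.dumps(db.report, sort_keys=True)}")
    except Exception as exc:  # noqa: BLE001 - rewrapped with section name
        fail("load", exc)

    simulations: dict[str, SimulationSummary] = {}
    try:
        spec = config.simulation_spec()
        simulations["overall"] = run_simulation(
            db, spec, hedges=config.hedges, standardizer=config.standardizer
        )
        for name, crit in config.sensitivity.items():
            sub = apply_filter(db, crit)
            log_lines.append(
                f"sensitivity {name}: {sub.n_studies} studies, "
                f"{sub.n_arms} arms"
            )
            simulations[name] = run_simulation(
                sub, spec, hedges=config.hedges,
                standardizer=config.standardizer,
            )
        fig2 = _fig2_frame(simulations)
        flush_csv("fig2_data.csv", fig2)
        fig3 = _fig3_frame(db, config.hedges, config.standardizer)
        flush_csv("fig3_data.csv", fig3)
        stab = simulations["overall"].stability
        stability_df = pd.DataFrame({
            "sim_count": np.arange(1, len(stab.z_values) + 1),
            "z": stab.z_values,
            "proportion_above": stab.cumulative_trace,
        })
        flush_csv("stability.csv", stability_df)
        per_sim = pd.concat(
            [s.per_sim.assign(analysis=k) for k, s in simulations.items()],
            ignore_index=True,
        )
        flush_csv("per_simulation.csv", per_sim)
        log_lines.append(
            f"stability: proportion_above={stab.proportion_above:.4f} "
            f"(threshold {stab.threshold})"
        )
    except ArmCompareError as exc:
        fail("simulation", exc)

    try:
        effects = compute_effects(db, REFERENCE_R, hedges=config.hedges,
                                  standardizer=config.standardizer)
        fracs = baseline_fractions(db)
        adj = rtm_adjusted_fit(effects, fracs)
        unadj = fit_multilevel(effects)
        rtm = {
            "r_reference": REFERENCE_R,
            "moderator": "baseline_fraction_c",
            "moderator_coefficient": adj.coefficients.get(
                "baseline_fraction_c"),
            "moderator_se": adj.se.get("baseline_fraction_c"),
            "adjusted_contrast": dict(zip(
                ("difference", "se", "z"),
                arm_type_contrast(adj, "medication_control",
                                  "psychotherapy_control"),
            )),
            "unadjusted_contrast": dict(zip(
                ("difference", "se", "z"),
                arm_type_contrast(unadj, "medication_control",
                                  "psychotherapy_control"),
            )),
        }
        flush_json("rtm.json", rtm)
    except ArmCompareError as exc:
        fail("rtm", exc)

    try:
        table1 = compare_baseline_characteristics(db, method=config.method)
        flush_csv("table1.csv", table1)
    except ArmCompareError as exc:
        fail("table1", exc)

    try:
        sites = compare_sites(db)
        flush_json("sites.json", sites)
    except ArmCompareError as exc:
        fail("sites", exc)

    try:
        table2 = compare_intensity(
            db, bonferroni_threshold=config.bonferroni_threshold
        )
        flush_csv("table2.csv", table2)
    except ArmCompareError as exc:
        fail("table2", exc)

    log_lines.append(f"written: {', '.join(written)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return ReportBundle(
        table1=table1, table2=table2, fig2_data=fig2, fig3_data=fig3,
        sites=sites, stability=stability_df, rtm=rtm,
        simulations=simulations,
    )
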