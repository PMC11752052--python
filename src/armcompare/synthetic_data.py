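"""Synthetic trial-database generator.

Emulates a ~92-trial evidence base of youth-depression RCTs with the
statistical structure the analysis assumes: modality-dependent baseline
severity (fractions of scale range ~0.42 medication vs ~0.37
psychotherapy), sex mix (~54% vs ~61% female), site counts (~36 vs ~3),
arm-type-specific true within-arm change SMDs with between-study and
between-arm heterogeneity, per-study pre-post correlations drawn
uniformly on (0.45, 0.9), session-intensity descriptors for
psychotherapy arms, and realistic missingness (post SD sometimes
absent, intensity often absent for control arms, the pre-post
correlation always absent).

Observed summary statistics are drawn from their exact sampling
distributions under normality: sample means are bivariate normal given
n and the true pre-post correlation, and sample SDs come from the
chi-square distribution with n-1 df, so dispersion-imputation rules are
exercised against statistically coherent inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trial_data import BUILTIN_SCALES, TrialDatabase

_TWO = ("medication", "psychotherapy")


def _mod_dict(med, psy):
    return {"medication": med, "psychotherapy": psy}


@dataclass
class GeneratorParams:
    """All generating parameters; serialized verbatim into truth.json.

    Control-arm true SMDs follow the reported evidence base (pill
    placebo -1.9, psychotherapy control -0.6); active-arm truths are
    assumptions (no published within-arm values), chosen to preserve
    plausible active-over-control improvement within each modality.
    """

    n_studies: dict = field(default_factory=lambda: _mod_dict(39, 53))
    true_smd: dict = field(
        default_factory=lambda: {
            "medication_active": -2.3,
            "medication_control": -1.9,
            "psychotherapy_active": -1.3,
            "psychotherapy_control": -0.6,
        }
    )
    sd_study: float = 0.3          # between-study SD of true SMDs
    sd_arm: float = 0.1            # between-arm-within-study SD
    r_low: float = 0.45            # per-study true pre-post correlation
    r_high: float = 0.9
    severity_mean: dict = field(default_factory=lambda: _mod_dict(0.42, 0.37))
    severity_sd: dict = field(default_factory=lambda: _mod_dict(0.05, 0.09))
    female_mean: dict = field(default_factory=lambda: _mod_dict(53.72, 61.36))
    female_sd: dict = field(default_factory=lambda: _mod_dict(12.3, 16.2))
    age_mean: dict = field(default_factory=lambda: _mod_dict(13.69, 14.3))
    age_sd: dict = field(default_factory=lambda: _mod_dict(1.9, 2.4))
    sites_mean: dict = field(default_factory=lambda: _mod_dict(36.0, 3.0))
    sites_sd: dict = field(default_factory=lambda: _mod_dict(25.0, 3.0))
    #: median per-arm n (log-normal, sigma 0.4), floors at 10
    arm_n_median: dict = field(default_factory=lambda: _mod_dict(90, 40))
    arm_n_sigma: float = 0.4
    p_cdrs: dict = field(default_factory=lambda: _mod_dict(0.7, 0.5))
    p_extra_active: float = 0.25
    p_extra_control: dict = field(default_factory=lambda: _mod_dict(0.0, 0.17))
    #: psychotherapy control mix, proportional to 14:28:20
    control_mix: dict = field(
        default_factory=lambda: {"waitlist": 14 / 62, "tau": 28 / 62,
                                 "other": 20 / 62}
    )
    subclinical_rate: dict = field(default_factory=lambda: _mod_dict(0.0, 0.15))
    n_all_female_psychotherapy: int = 2
    #: intensity distributions (mean, sd) for psychotherapy arms;
    #: control values are the target mixture moments with waitlist at 0
    intensity_active: dict = field(
        default_factory=lambda: {
            "n_sessions": (12.94, 11.02),
            "sessions_per_week": (1.28, 0.71),
            "session_minutes": (65.52, 31.63),
            "total_hours": (13.80, 9.88),
        }
    )
    intensity_control: dict = field(
        default_factory=lambda: {
            "n_sessions": (5.71, 6.10),
            "sessions_per_week": (0.58, 0.67),
            "session_minutes": (29.12, 35.01),
            "total_hours": (5.17, 7.63),
        }
    )
    intensity_missing_active: dict = field(
        default_factory=lambda: {
            "n_sessions": 0.0, "sessions_per_week": 0.08,
            "session_minutes": 0.15, "total_hours": 0.12,
        }
    )
    intensity_missing_control: dict = field(
        default_factory=lambda: {
            "n_sessions": 0.25, "sessions_per_week": 0.32,
            "session_minutes": 0.30, "total_hours": 0.32,
        }
    )
    missing_post_sd: float = 0.25
    missing_post_mean: float = 0.05
    missing_sites: dict = field(default_factory=lambda: _mod_dict(0.28, 0.15))
    missing_age: dict = field(default_factory=lambda: _mod_dict(0.28, 0.0))
    missing_female: dict = field(default_factory=lambda: _mod_dict(0.28, 0.04))
    pre_sd_frac_low: float = 0.08  # baseline SD as fraction of scale range
    pre_sd_frac_high: float = 0.14
    rtm_slope: float = 0.0         # extra true-SMD slope per severity-fraction unit
    waitlist_zero_intensity: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trunc_normal_int(rng, mean, sd, size, low=1):
    # clipping (not redrawing) keeps the mean near the nominal value
    return np.maximum(np.round(rng.normal(mean, sd, size)), low).astype(int)


def _sample_sd(rng, sigma, n):
    return float(sigma * np.sqrt(rng.chisquare(n - 1) / (n - 1)))


def generate_database(params: GeneratorParams | None = None) -> TrialDatabase:
    """Draw one full synthetic :class:`TrialDatabase`."""
    p = params or GeneratorParams()
    if p.sd_study < 0 or p.sd_arm < 0:
        raise ConfigError("heterogeneity SDs must be >= 0")
    rng = np.random.default_rng(p.seed)
    scales = dict(BUILTIN_SCALES)
    scale_names = list(scales)
    study_rows, arm_rows = [], []

    for modality in _TWO:
        n_stud = p.n_studies[modality]
        sites = _trunc_normal_int(
            rng, p.sites_mean[modality], p.sites_sd[modality], n_stud
        )
        for i in range(n_stud):
            sid = f"{modality[:3]}{i:03d}"
            scale = scales[
                scale_names[0] if rng.random() < p.p_cdrs[modality]
                else scale_names[1]
            ]
            frac = float(np.clip(
                rng.normal(p.severity_mean[modality], p.severity_sd[modality]),
                0.12, 0.85,
            ))
            all_female = (
                modality == "psychotherapy"
                and i < p.n_all_female_psychotherapy
            )
            female = 100.0 if all_female else float(np.clip(
                rng.normal(p.female_mean[modality], p.female_sd[modality]),
                0.0, 100.0,
            ))
            age = float(np.clip(
                rng.normal(p.age_mean[modality], p.age_sd[modality]), 6.0, 18.0
            ))
            sd_age = float(max(rng.normal(1.5, 0.3), 0.5))
            subclinical = bool(rng.random() < p.subclinical_rate[modality])
            r_study = float(rng.uniform(p.r_low, p.r_high))
            u_study = float(rng.normal(0.0, p.sd_study))

            roles = ["control", "active"]
            if rng.random() < p.p_extra_control[modality]:
                roles.append("control")
            if rng.random() < p.p_extra_active:
                roles.append("active")
            if modality == "medication":
                ctl_types = iter(["pill_placebo", "pill_placebo"])
            else:
                mix = p.control_mix
                kinds = list(mix)
                probs = np.array([mix[k] for k in kinds], dtype=float)
                probs /= probs.sum()
                ctl_types = iter(rng.choice(kinds, size=2, p=probs))

            n_total = 0
            for j, role in enumerate(roles):
                aid = f"{role[0]}{j}"
                n = int(max(10, round(
                    rng.lognormal(np.log(p.arm_n_median[modality]),
                                  p.arm_n_sigma)
                )))
                n_total += n
                ctl_type = "none" if role == "active" else next(ctl_types)
                smd_true = (
                    p.true_smd[f"{modality}_{role}"]
                    + u_study
                    + float(rng.normal(0.0, p.sd_arm))
                    + p.rtm_slope * (frac - p.severity_mean[modality])
                )
                mu_pre = scale.min_score + frac * scale.range
                sig_pre = float(
                    rng.uniform(p.pre_sd_frac_low, p.pre_sd_frac_high)
                    * scale.range
                )
                mu_post = mu_pre + smd_true * sig_pre
                sig_post = sig_pre * float(rng.uniform(0.9, 1.1))
                # sample means: bivariate normal given n and r_study
                m_pre = float(rng.normal(mu_pre, sig_pre / np.sqrt(n)))
                cond_mean = mu_post + r_study * (sig_post / sig_pre) * (
                    m_pre - mu_pre
                )
                cond_sd = sig_post * np.sqrt(1.0 - r_study**2) / np.sqrt(n)
                m_post = float(rng.normal(cond_mean, cond_sd))
                s_pre = _sample_sd(rng, sig_pre, n)
                s_post = _sample_sd(rng, sig_post, n)
                sd_change = float(np.sqrt(max(
                    s_pre**2 + s_post**2 - 2 * r_study * s_pre * s_post, 1e-12
                )))

                row = {
                    "study_id": sid, "arm_id": aid, "role": role,
                    "control_type": ctl_type, "n": n, "scale": scale.name,
                    "baseline_mean": m_pre, "baseline_sd": s_pre,
                    "post_mean": m_post, "post_sd": s_post,
                    "change_mean": np.nan, "change_sd": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "se_reported": np.nan, "t_reported": np.nan,
                    "p_reported": np.nan,
                    "n_sessions": np.nan, "session_minutes": np.nan,
                    "sessions_per_week": np.nan, "total_weeks": np.nan,
                    "total_hours": np.nan,
                }
                # missingness + alternative reporting of the change SD
                if rng.random() < p.missing_post_sd:
                    row["post_sd"] = np.nan
                    row["change_mean"] = m_post - m_pre
                    se_ch = sd_change / np.sqrt(n)
                    u = rng.random()
                    if u < 0.4:
                        row["se_reported"] = se_ch
                    elif u < 0.7:
                        row["ci_low"] = row["change_mean"] - 1.96 * se_ch
                        row["ci_high"] = row["change_mean"] + 1.96 * se_ch
                    elif u < 0.9:
                        row["t_reported"] = row["change_mean"] / se_ch
                    else:
                        row["change_sd"] = sd_change
                if rng.random() < p.missing_post_mean:
                    row["change_mean"] = m_post - m_pre
                    row["post_mean"] = np.nan

                if modality == "psychotherapy":
                    _fill_intensity(rng, p, row, role, ctl_type)
                arm_rows.append(row)

            study_rows.append({
                "study_id": sid, "modality": modality,
                "n_sites": (np.nan if rng.random() < p.missing_sites[modality]
                            else int(sites[i])),
                "subclinical": subclinical,
                "percent_female": (np.nan
                                   if (not all_female
                                       and rng.random() < p.missing_female[modality])
                                   else female),
                "mean_age": (np.nan if rng.random() < p.missing_age[modality]
                             else age),
                "sd_age": sd_age,
                "n_total": n_total,
            })

    studies = pd.DataFrame(study_rows)
    arms = pd.DataFrame(arm_rows)
    return TrialDatabase(studies, arms, scales)


def _fill_intensity(rng, p: GeneratorParams, row: dict, role: str,
                    ctl_type: str) -> None:
    if role == "active":
        dists, miss = p.intensity_active, p.intensity_missing_active
        wl_share = 0.0
    else:
        dists, miss = p.intensity_control, p.intensity_missing_control
        wl_share = p.control_mix.get("waitlist", 0.0) if \
            p.waitlist_zero_intensity else 0.0
    is_wl = ctl_type == "waitlist" and p.waitlist_zero_intensity
    for var, (mean, sd) in dists.items():
        if is_wl:
            # a waitlist has no sessions; session length stays unknown
            row[var] = np.nan if var == "session_minutes" else 0.0
            continue
        target = mean
        if role == "control" and var != "session_minutes" and wl_share < 1:
            target = mean / (1.0 - wl_share)  # mixture mean matches `mean`
        val = max(float(rng.normal(target, sd)), 0.0)
        row[var] = np.nan if rng.random() < miss[var] else val
    row["total_weeks"] = max(float(rng.normal(10.0, 4.0)), 1.0)


_FIXTURE_SEEDS = {
    "minimal_two_arm": None,
    "six_study_multilevel": 7,
    "paper_scale_default": 20240901,
    "null_no_modality_difference": 11,
    "rtm_slope": 23,
}


def null_params(seed: int = 11) -> GeneratorParams:
    """Both modalities share every generating parameter (no true
    modality difference in SMDs, severity, sex, age or sites), waitlists
    removed and control intensity equal to active intensity — the null
    configuration for calibration checks."""
    p = GeneratorParams(seed=seed)
    p.true_smd = {
        "medication_active": -1.0, "medication_control": -1.0,
        "psychotherapy_active": -1.0, "psychotherapy_control": -1.0,
    }
    for d in (p.severity_mean, p.severity_sd, p.female_mean, p.female_sd,
              p.age_mean, p.age_sd, p.sites_mean, p.sites_sd,
              p.arm_n_median, p.p_cdrs, p.subclinical_rate,
              p.missing_sites, p.missing_age, p.missing_female,
              p.p_extra_control):
        d["medication"] = d["psychotherapy"]
    p.n_studies = {"medication": 39, "psychotherapy": 53}
    p.control_mix = {"waitlist": 0.0, "tau": 1.0, "other": 0.0}
    p.intensity_control = dict(p.intensity_active)
    p.intensity_missing_control = dict(p.intensity_missing_active)
    p.n_all_female_psychotherapy = 0
    return p


def make_fixture(name: str, seed: int | None = None) -> TrialDatabase:
    """Named deterministic fixture databases used across the test suites."""
    if name not in _FIXTURE_SEEDS:
        raise ConfigError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_SEEDS)}"
        )
    seed = _FIXTURE_SEEDS[name] if seed is None else seed
    if name == "minimal_two_arm":
        studies = pd.DataFrame([{
            "study_id": "med000", "modality": "medication", "n_sites": 12,
            "subclinical": False, "percent_female": 50.0, "mean_age": 14.0,
            "sd_age": 1.5, "n_total": 180,
        }])
        arms = pd.DataFrame([
            {"study_id": "med000", "arm_id": "c0", "role": "control",
             "control_type": "pill_placebo", "n": 90, "scale": "CDRS-R",
             "baseline_mean": 57.3, "baseline_sd": 10.0, "post_mean": 38.3,
             "post_sd": 11.0},
            {"study_id": "med000", "arm_id": "a1", "role": "active",
             "control_type": "none", "n": 90, "scale": "CDRS-R",
             "baseline_mean": 57.0, "baseline_sd": 9.5, "post_mean": 35.0,
             "post_sd": 10.5},
        ])
        return TrialDatabase(studies, arms)
    if name == "six_study_multilevel":
        p = GeneratorParams(seed=seed)
        p.n_studies = {"medication": 3, "psychotherapy": 3}
        p.missing_post_sd = 0.0
        p.missing_post_mean = 0.0
        return generate_database(p)
    if name == "paper_scale_default":
        return generate_database(GeneratorParams(seed=seed))
    if name == "null_no_modality_difference":
        return generate_database(null_params(seed))
    if name == "rtm_slope":
        # large arms so baseline sampling noise (shared between the
        # observed severity fraction and the SMD) cannot bias the slope
        p = GeneratorParams(seed=seed)
        p.rtm_slope = -2.0
        p.arm_n_median = {"medication": 2000, "psychotherapy": 2000}
        p.missing_post_sd = 0.0
        p.missing_post_mean = 0.0
        return generate_database(p)
    raise AssertionError("unreachable")
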