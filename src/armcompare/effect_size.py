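"""Within-arm pre-post standardized mean differences.

The effect measure is the within-group change between baseline and
endpoint on the study's primary depression scale, standardized by the
baseline SD (Becker-type estimator):

    d = (m_post - m_pre) / s_pre,          negative = improvement,

with large-sample sampling variance

    var(d) = 2(1 - r)/n + d^2/(2n),

where r is the (rarely reported) correlation between a participant's
baseline and endpoint scores.  The point estimate is r-free; only the
variance depends on r, which is why r-uncertainty is propagated by
simulation rather than by a single imputed value.  A change-score
standardizer (d = change_mean / sd_change, var = 1/n + d^2/(2n)) is
available behind ``standardizer="change"`` for sensitivity work.

Missing dispersion statistics are recovered with the standard
summary-statistic conversions (SE, confidence interval, t statistic,
two-sided p, or the pre/post-SD identity), with every rule that fired
recorded as provenance flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ImputationError
from .trial_data import ScaleSpec, TrialDatabase

ARM_TYPES = (
    "medication_active",
    "medication_control",
    "psychotherapy_active",
    "psychotherapy_control",
)


class SeverityFraction(NamedTuple):
    """A scale score expressed as a fraction of the scale's range."""

    value: float
    scale: ScaleSpec

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ArmEffect:
    study_id: str
    arm_id: str
    arm_type: str
    smd: float
    variance: float
    r_used: float
    imputation_flags: frozenset[str]


def score_to_fraction(score: float, scale: ScaleSpec) -> SeverityFraction:
    """Map a raw scale score onto [0, 1] as a fraction of the scale range."""
    if not (scale.min_score <= score <= scale.max_score):
        raise DomainError(
            f"score {score} outside {scale.name} bounds "
            f"[{scale.min_score}, {scale.max_score}]"
        )
    return SeverityFraction((score - scale.min_score) / scale.range, scale)


def fraction_to_score(fraction: float | SeverityFraction,
                      scale: ScaleSpec | None = None) -> float:
    """Inverse of :func:`score_to_fraction`: fraction -> raw scale score."""
    if isinstance(fraction, SeverityFraction):
        scale = fraction.scale
        fraction = fraction.value
    if scale is None:
        raise DomainError("a scale is required to map a bare fraction")
    if not (0.0 <= fraction <= 1.0):
        raise DomainError(f"fraction {fraction} outside [0, 1]")
    return scale.min_score + fraction * scale.range


def hedges_j(n: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4(n-1) - 1)."""
    return 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)


def _get(arm: Mapping, key: str) -> float:
    v = arm.get(key) if hasattr(arm, "get") else arm[key]
    if v is None:
        return np.nan
    return float(v) if not isinstance(v, str) else np.nan


def impute_dispersion(arm: Mapping, r: float) -> tuple[float, frozenset[str]]:
    """Recover the SD of the pre-post change score for one arm.

    Rules are tried in priority order; the first applicable one wins and
    every rule fired is recorded:

    1. reported ``change_sd``;
    2. ``sd = se_reported * sqrt(n)``;
    3. ``sd = ((ci_high - ci_low)/3.92) * sqrt(n)`` (95% CI of the change);
    4. ``se = |change_mean| / |t_reported|``, then rule 2;
    5. recover |t| from a two-sided p with n-1 df, then rule 4;
    6. ``sd = sqrt(sd_pre^2 + sd_post^2 - 2 r sd_pre sd_post)``.
    """
    n = _get(arm, "n")
    label = f"{arm['study_id']}/{arm['arm_id']}"
    change_sd = _get(arm, "change_sd")
    if np.isfinite(change_sd):
        return change_sd, frozenset()
    se = _get(arm, "se_reported")
    if np.isfinite(se):
        return se * np.sqrt(n), frozenset({"sd_from_se"})
    lo, hi = _get(arm, "ci_low"), _get(arm, "ci_high")
    if np.isfinite(lo) and np.isfinite(hi):
        return ((hi - lo) / 3.92) * np.sqrt(n), frozenset({"sd_from_ci"})
    change_mean = _get(arm, "change_mean")
    if not np.isfinite(change_mean):
        post, base = _get(arm, "post_mean"), _get(arm, "baseline_mean")
        change_mean = post - base
    t = _get(arm, "t_reported")
    if np.isfinite(t):
        if t == 0 and change_mean != 0:
            raise ImputationError(
                f"{label}: t_reported = 0 with nonzero change"
            )
        return abs(change_mean) / abs(t) * np.sqrt(n), frozenset({"sd_from_t"})
    p = _get(arm, "p_reported")
    if np.isfinite(p):
        t_abs = stats.t.isf(p / 2.0, df=n - 1)
        if t_abs == 0:
            raise ImputationError(f"{label}: p_reported = 1 is degenerate")
        return (
            abs(change_mean) / t_abs * np.sqrt(n),
            frozenset({"sd_from_p", "sd_from_t"}),
        )
    sd_pre, sd_post = _get(arm, "baseline_sd"), _get(arm, "post_sd")
    if np.isfinite(sd_pre) and np.isfinite(sd_post):
        var = sd_pre**2 + sd_post**2 - 2.0 * r * sd_pre * sd_post
        return np.sqrt(max(var, 0.0)), frozenset({"change_sd_from_r"})
    raise ImputationError(f"{label}: no applicable dispersion rule")


def prepost_smd(
    arm: Mapping,
    modality: str,
    r: float,
    hedges: bool = True,
    standardizer: str = "baseline",
) -> ArmEffect:
    """Pre-post SMD with variance for one arm.

    ``arm`` is any mapping with the arm CSV fields (a pandas Series row
    works).  ``modality`` comes from the parent study and fixes the arm
    type.  Negative SMDs mean symptom improvement.
    """
    if not (0.0 < r < 1.0):
        raise DomainError(f"correlation r={r} outside (0, 1)")
    n = _get(arm, "n")
    if not np.isfinite(n) or n < 2:
        raise DomainError(f"arm n={n} too small for an SMD")
    n = int(n)
    base_mean = _get(arm, "baseline_mean")
    base_sd = _get(arm, "baseline_sd")
    flags: frozenset[str] = frozenset()

    post_mean = _get(arm, "post_mean")
    change_mean = _get(arm, "change_mean")
    if not np.isfinite(change_mean):
        change_mean = post_mean - base_mean

    if standardizer == "baseline":
        if not np.isfinite(base_sd) or base_sd <= 0:
            raise DomainError(
                f"{arm['study_id']}/{arm['arm_id']}: baseline_sd must be > 0"
            )
        d = change_mean / base_sd
        variance_fn = lambda d_: 2.0 * (1.0 - r) / n + d_**2 / (2.0 * n)
    elif standardizer == "change":
        sd_change, flags = impute_dispersion(arm, r)
        if sd_change <= 0:
            raise DomainError(
                f"{arm['study_id']}/{arm['arm_id']}: change SD must be > 0"
            )
        d = change_mean / sd_change
        variance_fn = lambda d_: 1.0 / n + d_**2 / (2.0 * n)
    else:
        raise DomainError(f"unknown standardizer {standardizer!r}")

    if hedges:
        d *= hedges_j(n)
    variance = variance_fn(d)
    role = arm["role"]
    return ArmEffect(
        study_id=str(arm["study_id"]),
        arm_id=str(arm["arm_id"]),
        arm_type=f"{modality}_{role}",
        smd=float(d),
        variance=float(variance),
        r_used=float(r),
        imputation_flags=flags,
    )


def compute_effects(
    db: TrialDatabase,
    r: float | Mapping[str, float],
    hedges: bool = True,
    standardizer: str = "baseline",
) -> pd.DataFrame:
    """Effects for every arm of ``db`` as a tidy DataFrame.

    ``r`` is either one correlation shared by all studies or a mapping
    from study_id to a per-study correlation.  Columns: study_id,
    arm_id, arm_type, smd, variance, r_used, imputation_flags.
    """
    modality = db.studies.set_index("study_id")["modality"]
    rows = []
    for _, arm in db.arms.iterrows():
        sid = arm["study_id"]
        r_i = float(r[sid]) if isinstance(r, Mapping) else float(r)
        eff = prepost_smd(arm, modality[sid], r_i, hedges=hedges,
                          standardizer=standardizer)
        rows.append(
            {
                "study_id": eff.study_id,
                "arm_id": eff.arm_id,
                "arm_type": eff.arm_type,
                "smd": eff.smd,
                "variance": eff.variance,
                "r_used": eff.r_used,
                "imputation_flags": "|".join(sorted(eff.imputation_flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id", "arm_id", "arm_type", "smd", "variance",
            "r_used", "imputation_flags",
        ],
    )


def baseline_fractions(db: TrialDatabase) -> pd.Series:
    """Per-arm baseline severity as a fraction of the arm's scale range,
    indexed like ``db.arms``."""
    vals = []
    for _, arm in db.arms.iterrows():
        scale = db.scale_of(arm["scale"])
        vals.append(
            score_to_fraction(float(arm["baseline_mean"]), scale).value
        )
    return pd.Series(vals, index=db.arms.index, name="baseline_fraction")
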