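"""Generic inverse-variance random-effects meta-analysis and two-sample
summary-statistic comparisons, implemented from first principles.

Model: y_i = mu + u_i + e_i with u_i ~ N(0, tau^2) and e_i ~ N(0, v_i),
v_i known.  tau^2 is estimated by restricted maximum likelihood (the
default) or the DerSimonian-Laird moment estimator; the pooled mean is
the inverse-variance weighted average under weights 1/(v_i + tau^2).

Also provides the between-subgroup heterogeneity Q test, the Welch
unequal-variance t-test, and pooled-SD Cohen's d from group summary
statistics — the toolkit needed to compare sample and trial
characteristics across treatment modalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import DomainError

Z95 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate for one subgroup/characteristic."""

    k: int
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    method: str


@dataclass(frozen=True)
class SubgroupComparison:
    results: Mapping[str, MetaResult]
    q_between: float
    df: int
    p: float


@dataclass(frozen=True)
class TwoSampleComparison:
    k1: int
    k2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    df: float
    p: float
    d: float
    d_ci_low: float
    d_ci_high: float


def _reml_negll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2))
        + np.log(np.sum(w))
        + np.sum(w * (y - mu) ** 2)
    )


def reml_tau2(y: np.ndarray, v: np.ndarray, upper: float | None = None) -> float:
    """REML tau^2 by bounded scalar minimization of the restricted
    negative log-likelihood, checking the tau^2 = 0 boundary."""
    if upper is None:
        upper = max(10.0 * float(np.var(y)), 100.0 * float(np.max(v)), 1.0)
    res = optimize.minimize_scalar(
        _reml_negll, args=(y, v), bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    if _reml_negll(0.0, y, v) <= _reml_negll(tau2, y, v):
        return 0.0
    return tau2


def dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird tau^2 and the fixed-effect Q statistic."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    k = len(y)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    return tau2, q


class RandomEffectsMeta(BaseEstimator):
    """Random-effects meta-analysis estimator.

    Parameters
    ----------
    method : {"REML", "DL", "FE"}
        Between-study variance estimator; "FE" forces tau^2 = 0.
    knapp_hartung : bool
        Use the t quantile with k-1 df and the Knapp-Hartung variance
        scaling for the CI instead of the normal quantile.
    alpha : float
        CI level is 1 - alpha.

    Attributes (after ``fit``)
    --------------------------
    k_, pooled_, se_, ci_low_, ci_high_, tau2_, q_ : float
    """

    def __init__(self, method: str = "REML", knapp_hartung: bool = False,
                 alpha: float = 0.05):
        self.method = method
        self.knapp_hartung = knapp_hartung
        self.alpha = alpha

    def fit(self, y, v):
        y = np.asarray(y, dtype=float).ravel()
        v = np.asarray(v, dtype=float).ravel()
        if len(y) == 0:
            raise DomainError("cannot pool an empty set of estimates")
        if len(y) != len(v):
            raise DomainError("estimates and variances differ in length")
        if np.any(v <= 0):
            raise DomainError("all sampling variances must be > 0")
        if self.method not in ("REML", "DL", "FE"):
            raise DomainError(f"unknown pooling method {self.method!r}")
        k = len(y)
        if k == 1:
            tau2, q = 0.0, 0.0
        else:
            _, q = dl_tau2(y, v)
            if self.method == "DL":
                tau2 = dl_tau2(y, v)[0]
            elif self.method == "REML":
                tau2 = reml_tau2(y, v)
            else:
                tau2 = 0.0
        w = 1.0 / (v + tau2)
        pooled = float(np.sum(w * y) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        if self.knapp_hartung and k > 1:
            scale = np.sum(w * (y - pooled) ** 2) / (k - 1)
            se = float(se * np.sqrt(max(scale, 1.0)))
            crit = stats.t.ppf(1.0 - self.alpha / 2.0, df=k - 1)
        else:
            crit = stats.norm.ppf(1.0 - self.alpha / 2.0)
        self.k_ = k
        self.tau2_ = float(tau2)
        self.q_ = float(q)
        self.pooled_ = pooled
        self.se_ = se
        self.ci_low_ = pooled - crit * se
        self.ci_high_ = pooled + crit * se
        return self

    def result_(self) -> MetaResult:
        return MetaResult(
            k=self.k_, pooled=self.pooled_, se=self.se_,
            ci_low=self.ci_low_, ci_high=self.ci_high_,
            tau2=self.tau2_, q=self.q_, method=self.method,
        )


def pool_random_effects(
    estimates: Sequence[tuple[float, float]] | np.ndarray,
    method: str = "REML",
    knapp_hartung: bool = False,
) -> MetaResult:
    """Pool (value, variance) pairs; thin wrapper over
    :class:`RandomEffectsMeta`."""
    arr = np.asarray(estimates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("estimates must be (value, variance) pairs")
    est = RandomEffectsMeta(method=method, knapp_hartung=knapp_hartung)
    est.fit(arr[:, 0], arr[:, 1])
    return est.result_()


def subgroup_difference(
    results: Mapping[str, MetaResult],
) -> SubgroupComparison:
    """Between-subgroup heterogeneity Q test on pooled subgroup means.

    Q_between = sum_g w_g (theta_g - theta_bar)^2 with w_g = 1/se_g^2,
    referred to chi-square with G-1 df.
    """
    if len(results) < 2:
        raise DomainError("need at least two subgroups")
    theta = np.array([r.pooled for r in results.values()])
    se = np.array([r.se for r in results.values()])
    if np.any(se == 0):
        raise DomainError("subgroup with zero SE is degenerate")
    w = 1.0 / se**2
    theta_bar = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - theta_bar) ** 2))
    df = len(results) - 1
    p = float(stats.chi2.sf(q, df))
    return SubgroupComparison(results=dict(results), q_between=q, df=df, p=p)


def cohens_d_pooled(
    k1: int, mean1: float, sd1: float, k2: int, mean2: float, sd2: float,
) -> tuple[float, float, float]:
    """Cohen's d with pooled SD and its large-sample 95% CI.

    var(d) = (k1+k2)/(k1 k2) + d^2 / (2(k1+k2)).
    """
    if k1 + k2 < 3:
        raise DomainError("need k1 + k2 >= 3 for a pooled SD")
    sp2 = ((k1 - 1) * sd1**2 + (k2 - 1) * sd2**2) / (k1 + k2 - 2)
    if sp2 <= 0:
        raise DomainError("pooled SD is zero; d undefined")
    d = (mean1 - mean2) / np.sqrt(sp2)
    var_d = (k1 + k2) / (k1 * k2) + d**2 / (2.0 * (k1 + k2))
    half = Z95 * np.sqrt(var_d)
    return float(d), float(d - half), float(d + half)


def welch_t(
    k1: int, mean1: float, sd1: float, k2: int, mean2: float, sd2: float,
) -> TwoSampleComparison:
    """Welch unequal-variance t-test from group summary statistics,
    with pooled-SD Cohen's d attached."""
    if k1 < 2 or k2 < 2:
        raise DomainError("each group needs k >= 2")
    if sd1 == 0 and sd2 == 0:
        raise DomainError("both SDs zero: t undefined")
    se2_1 = sd1**2 / k1
    se2_2 = sd2**2 / k2
    t = (mean1 - mean2) / np.sqrt(se2_1 + se2_2)
    df = (se2_1 + se2_2) ** 2 / (
        se2_1**2 / (k1 - 1) + se2_2**2 / (k2 - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    d, dlo, dhi = cohens_d_pooled(k1, mean1, sd1, k2, mean2, sd2)
    return TwoSampleComparison(
        k1=k1, k2=k2, mean1=mean1, mean2=mean2, sd1=sd1, sd2=sd2,
        t=float(t), df=float(df), p=float(p),
        d=d, d_ci_low=dlo, d_ci_high=dhi,
    )
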