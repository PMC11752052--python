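"""Three-level REML meta-regression against closed forms, a brute-force
restricted-likelihood grid, and an independent R/metafor fit."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from armcompare.effect_size import compute_effects
from armcompare.errors import ContrastError, CoverageError, DesignError
from armcompare.meta_core import RandomEffectsMeta
from armcompare.multilevel import (
    MultilevelMetaRegression,
    _BlockREML,
    arm_type_contrast,
    arm_type_design,
    fit_multilevel,
    rtm_adjusted_fit,
)
from armcompare.synthetic_data import make_fixture


def _dense_restricted_ll(y, v, X, study_idx, s2_study, s2_arm):
    """Independent dense-matrix restricted log-likelihood."""
    n, p = X.shape
    V = np.diag(v + s2_arm)
    for j in np.unique(study_idx):
        m = study_idx == j
        V[np.ix_(m, m)] += s2_study
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        + r @ Vinv @ r
    )


@pytest.fixture(scope="module")
def six_effects(six_study_db):
    return compute_effects(six_study_db, r=0.675)


def _design(effects):
    X, names = arm_type_design(effects)
    y = effects["smd"].to_numpy()
    v = effects["variance"].to_numpy()
    sid = pd.factorize(effects["study_id"])[0]
    return y, v, X, sid, names


class TestAgainstClosedForms:
    def test_one_arm_per_study_collapses_to_random_effects(self):
        rng = np.random.default_rng(8)
        y = rng.normal(-1.0, 0.4, size=12)
        v = rng.uniform(0.01, 0.05, size=12)
        eff = pd.DataFrame({
            "study_id": [f"s{i}" for i in range(12)],
            "arm_type": "medication_control", "smd": y, "variance": v,
        })
        fit = fit_multilevel(eff, fix_sigma2_arm=0.0)
        uni = RandomEffectsMeta(method="REML").fit(y, v)
        assert fit.coefficients["medication_control"] == pytest.approx(
            uni.pooled_, abs=1e-6
        )
        assert fit.sigma2_study == pytest.approx(uni.tau2_, abs=1e-6)
        assert fit.se["medication_control"] == pytest.approx(uni.se_, abs=1e-6)

    def test_zero_components_equal_wls(self, six_effects):
        y, v, X, sid, names = _design(six_effects)
        est = MultilevelMetaRegression(fix_sigma2_study=0.0, fix_sigma2_arm=0.0)
        est.fit(y, v, X, sid, names)
        W = np.diag(1.0 / v)
        beta_wls = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        np.testing.assert_allclose(est.coef_, beta_wls, rtol=1e-10)

    def test_dense_and_blockwise_likelihoods_agree(self, six_effects):
        y, v, X, sid, _ = _design(six_effects)
        engine = _BlockREML(y, v, X, sid, sid.max() + 1)
        for s2s, s2a in [(0.0, 0.0), (0.05, 0.01), (0.3, 0.2)]:
            ll, _, _ = engine.loglik(s2s, s2a)
            assert ll == pytest.approx(
                _dense_restricted_ll(y, v, X, sid, s2s, s2a), abs=1e-8
            )


def test_reml_matches_brute_force_grid(six_effects):
    """REML variance components equal the argmax of the restricted
    likelihood over a 2-D lattice at 1e-3 resolution."""
    y, v, X, sid, names = _design(six_effects)
    fit = fit_multilevel(six_effects)
    engine = _BlockREML(y, v, X, sid, sid.max() + 1)
    grid = np.arange(0.0, 0.2000001, 1e-3)
    best, arg = -np.inf, (None, None)
    for s2s in grid:
        for s2a in grid:
            ll, _, _ = engine.loglik(s2s, s2a)
            if ll > best:
                best, arg = ll, (s2s, s2a)
    # lattice edge check: optimum must be interior to the searched box
    assert arg[0] < 0.19 and arg[1] < 0.19
    assert fit.sigma2_study == pytest.approx(arg[0], abs=1.5e-3)
    assert fit.sigma2_arm == pytest.approx(arg[1], abs=1.5e-3)
    assert fit.loglik_reml >= best - 1e-9


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_cross_check_against_metafor(six_effects, tmp_path):
    """Independent oracle: metafor's rma.mv with random = ~1|study/arm."""
    csv = tmp_path / "eff.csv"
    six_effects.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
        suppressMessages(library(metafor))
        d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
        d$arm <- paste(d$study_id, d$arm_id)
        f <- rma.mv(smd, variance, mods = ~ arm_type - 1,
                    random = ~ 1 | study_id/arm, data = d)
        cat(jsonlite::toJSON(list(
          names = sub("arm_type", "", rownames(f$b)),
          beta = as.numeric(f$b), se = as.numeric(f$se),
          sigma2 = f$sigma2, ll = as.numeric(logLik(f))), digits=12))
        """
    )
    out = subprocess.run(
        ["Rscript", str(script), str(csv)],
        capture_output=True, text=True, timeout=300,
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    fit = fit_multilevel(six_effects)
    for name, beta, se in zip(ref["names"], ref["beta"], ref["se"]):
        assert fit.coefficients[name] == pytest.approx(beta, abs=1e-5)
        assert fit.se[name] == pytest.approx(se, abs=1e-5)
    assert fit.sigma2_study == pytest.approx(ref["sigma2"][0], abs=1e-5)
    assert fit.sigma2_arm == pytest.approx(ref["sigma2"][1], abs=1e-5)
    # metafor's REML loglik convention adds the constant 0.5 log|X'X|
    y, v, X, sid, names = _design(six_effects)
    offset = 0.5 * np.linalg.slogdet(X.T @ X)[1]
    assert fit.loglik_reml + offset == pytest.approx(ref["ll"][0], abs=1e-5)


def test_parameterization_invariance(six_effects):
    y, v, X, sid, names = _design(six_effects)
    est1 = MultilevelMetaRegression().fit(y, v, X, sid, names)
    # intercept + treatment contrasts spans the same column space
    X2 = np.column_stack([np.ones(len(y)), X[:, 1:]])
    est2 = MultilevelMetaRegression().fit(
        y, v, X2, sid, ["intercept"] + names[1:]
    )
    assert est1.sigma2_study_ == pytest.approx(est2.sigma2_study_, abs=1e-6)
    assert est1.sigma2_arm_ == pytest.approx(est2.sigma2_arm_, abs=1e-6)
    np.testing.assert_allclose(X @ est1.coef_, X2 @ est2.coef_, atol=1e-8)


def test_profile_perturbation_never_improves(six_effects, paper_db):
    for effects in (six_effects, compute_effects(paper_db, r=0.6)):
        y, v, X, sid, names = _design(effects)
        est = MultilevelMetaRegression().fit(y, v, X, sid, names)
        engine = _BlockREML(y, v, X, pd.factorize(effects["study_id"])[0],
                            effects["study_id"].nunique())
        ll_opt = est.loglik_reml_
        for fs in (0.9, 1.1):
            for fa in (0.9, 1.1):
                ll, _, _ = engine.loglik(
                    est.sigma2_study_ * fs, est.sigma2_arm_ * fa
                )
                assert ll <= ll_opt + 1e-7


class TestContrasts:
    def test_self_contrast_is_zero(self, six_effects):
        fit = fit_multilevel(six_effects)
        d, se, z = arm_type_contrast(
            fit, "medication_control", "medication_control"
        )
        assert d == 0.0 and z == 0.0

    def test_missing_arm_type(self, six_effects):
        fit = fit_multilevel(six_effects)
        with pytest.raises(ContrastError):
            arm_type_contrast(fit, "medication_control", "nonexistent")

    def test_control_arm_gap_detected_on_paper_scale(self, paper_db):
        fit = fit_multilevel(compute_effects(paper_db, r=0.675))
        d, se, z = arm_type_contrast(
            fit, "psychotherapy_control", "medication_control"
        )
        assert d == pytest.approx(1.3, abs=0.25)  # -0.6 - (-1.9)
        assert z > 1.645

    def test_se_formula(self, six_effects):
        fit = fit_multilevel(six_effects)
        ia = fit.names.index("medication_active")
        ib = fit.names.index("psychotherapy_active")
        _, se, _ = arm_type_contrast(
            fit, "medication_active", "psychotherapy_active"
        )
        expect = np.sqrt(
            fit.vcov[ia, ia] + fit.vcov[ib, ib] - 2 * fit.vcov[ia, ib]
        )
        assert se == pytest.approx(expect, rel=1e-12)


def test_rank_deficient_design_named(six_effects):
    y, v, X, sid, names = _design(six_effects)
    X2 = np.column_stack([X, X[:, 0]])
    with pytest.raises(DesignError, match="collinear"):
        MultilevelMetaRegression().fit(y, v, X2, sid, names + ["dup"])


class TestRegressionToTheMean:
    def test_constant_baseline_drops_moderator(self, six_effects):
        with pytest.warns(UserWarning, match="constant"):
            fit = rtm_adjusted_fit(
                six_effects, np.full(len(six_effects), 0.4)
            )
        plain = fit_multilevel(six_effects)
        assert fit.coefficients == pytest.approx(plain.coefficients)

    def test_missing_baselines_rejected(self, six_effects):
        base = np.full(len(six_effects), 0.4)
        base[0] = np.nan
        with pytest.raises(CoverageError):
            rtm_adjusted_fit(six_effects, base)

    def test_recovers_generated_baseline_slope(self):
        from armcompare.effect_size import baseline_fractions

        db = make_fixture("rtm_slope")  # change depends on baseline, slope -2
        eff = compute_effects(db, r=0.675)
        fit = rtm_adjusted_fit(eff, baseline_fractions(db))
        b = fit.coefficients["baseline_fraction_c"]
        se = fit.se["baseline_fraction_c"]
        assert b - 1.96 * se < -2.0 < b + 1.96 * se

    def test_permuted_moderator_covers_zero(self):
        from armcompare.effect_size import baseline_fractions

        db = make_fixture("rtm_slope")
        eff = compute_effects(db, r=0.675)
        base = baseline_fractions(db).to_numpy()
        rng = np.random.default_rng(99)
        covered = 0
        n_perm = 200
        for _ in range(n_perm):
            fit = rtm_adjusted_fit(eff, rng.permutation(base), n_starts=1)
            b = fit.coefficients["baseline_fraction_c"]
            se = fit.se["baseline_fraction_c"]
            if b - 1.96 * se <= 0.0 <= b + 1.96 * se:
                covered += 1
        assert covered / n_perm >= 0.90
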