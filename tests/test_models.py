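"""Estimation machinery: bivariate-normal CDF against quadrature, probit
closed forms and recovery, FIML endogenous-treatment identities and the
market-share instrument."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal
from statsmodels.discrete.discrete_model import Probit

import kidneytp as ktp
from kidneytp.models import ConvergenceError, _design

SPEC = ktp.ModelSpec(outcome="survival_1yr", treatment="tp",
                     step1_covariates=["age", "kdpi", "epts"],
                     controls=["kdpi", "age", "epts"])


def test_bvn_cdf_matches_quadrature_oracle():
    rng = np.random.default_rng(0)
    for _ in range(40):
        h, k = rng.normal(size=2) * 2
        r = rng.uniform(-0.95, 0.95)
        ref = multivariate_normal([0, 0], [[1, r], [r, 1]]).cdf([h, k])
        assert float(ktp.bvn_cdf(h, k, r)) == pytest.approx(ref, abs=1e-8)
    # independence and boundary structure
    assert float(ktp.bvn_cdf(0.3, -0.2, 0.0)) == pytest.approx(
        stats.norm.cdf(0.3) * stats.norm.cdf(-0.2), abs=1e-10)
    assert float(ktp.bvn_cdf(0.0, 0.0, 0.5)) == pytest.approx(
        0.25 + np.arcsin(0.5) / (2 * np.pi), abs=1e-7)


def test_probit_intercept_only_closed_form():
    df = pd.DataFrame({"y": [0, 1] * 100})
    r = ktp.fit_probit(df, "y", [])
    assert r.params["const"] == pytest.approx(0.0, abs=1e-6)  # Phi^-1(0.5)


def test_probit_recovers_known_coefficients():
    rng = np.random.default_rng(1)
    n = 20000
    x = rng.normal(size=n)
    y = (0.5 + 1.2 * x + rng.normal(size=n) > 0).astype(int)
    r = ktp.fit_probit(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
    assert abs(r.params["x"] - 1.2) < 2 * r.bse["x"]
    assert abs(r.params["const"] - 0.5) < 2 * r.bse["const"]


def test_probit_type_i_error_calibrated():
    """Slope z-test rejects at ~5% under the null, over 200 replicates."""
    rng = np.random.default_rng(2)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.normal(size=800)
        y = (rng.random(800) < 0.5).astype(int)
        r = ktp.fit_probit(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        z = r.params["x"] / r.bse["x"]
        rejections += abs(z) > 1.96
    rate = rejections / n_rep
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < 3 * se


def test_perfect_separation_raises():
    df = pd.DataFrame({"y": [0] * 20 + [1] * 20,
                       "x": np.r_[np.zeros(20), np.ones(20)]})
    with pytest.raises(ConvergenceError, match="separation"):
        ktp.fit_probit(df, "y", ["x"])


def test_collinear_column_dropped_with_warning():
    df = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
    with pytest.warns(UserWarning, match="collinear"):
        X, names = _design(df, ["a", "b"])
    assert names == ["const", "a"]


def test_joint_loglike_factorizes_at_rho_zero():
    """At rho = 0 the FIML log-likelihood equals the sum of the two
    single-equation probit log-likelihoods."""
    df, _ = ktp.simulate_transplant_table(3000, beta1=0.2, rho=0.4, seed=5)
    est = ktp.EndogenousTreatmentProbit(SPEC)
    y = df["survival_1yr"].to_numpy(float)
    t = df["tp"].to_numpy(float)
    X, _ = _design(df, list(SPEC.controls))
    Z, _ = _design(df, list(SPEC.step1_covariates))
    p_t = Probit(t, Z).fit(disp=0)
    p_y = Probit(y, np.hstack([X, t[:, None]])).fit(disp=0)
    theta = np.concatenate([p_y.params[:-1], [p_y.params[-1]], p_t.params, [0.0]])
    joint = est._loglike_obs(theta, X, Z, y, t).sum()
    assert joint == pytest.approx(p_t.llf + p_y.llf, rel=1e-8)


def test_analytic_score_matches_finite_differences():
    df, _ = ktp.simulate_transplant_table(500, beta1=0.3, rho=0.3, seed=6)
    est = ktp.EndogenousTreatmentProbit(SPEC)
    y = df["survival_1yr"].to_numpy(float)
    t = df["tp"].to_numpy(float)
    X, _ = _design(df, list(SPEC.controls))
    Z, _ = _design(df, list(SPEC.step1_covariates))
    theta = np.r_[0.5, -0.5, 0.01, -0.3, 0.1, -2.0, 0.02, 0.3, -0.5, 0.2]
    grad = est._score(theta, X, Z, y, t)
    eps = 1e-6
    for j in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        fd = (est._loglike_obs(tp, X, Z, y, t).sum()
              - est._loglike_obs(tm, X, Z, y, t).sum()) / (2 * eps)
        assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-4)


def test_endogenous_collapses_to_exogenous_when_rho_zero():
    df, _ = ktp.simulate_transplant_table(20000, beta1=0.3, rho=0.0, seed=7)
    endo = ktp.fit_treatment_probit(df, SPEC, "endogenous")
    exo = ktp.fit_treatment_probit(df, SPEC, "exogenous")
    joint_se = np.hypot(endo.treatment_se, exo.treatment_se)
    assert abs(endo.treatment_coefficient - exo.treatment_coefficient) < 2 * joint_se
    assert abs(endo.rho) < 2 * endo.rho_se


def test_endogenous_undoes_confounding_exogenous_does_not():
    """The motivating scenario: no true effect, correlated errors."""
    df, _ = ktp.simulate_transplant_table(20000, beta1=0.0, rho=0.5, seed=8)
    exo = ktp.fit_treatment_probit(df, SPEC, "exogenous")
    endo = ktp.fit_treatment_probit(df, SPEC, "endogenous")
    assert exo.treatment_coefficient / exo.treatment_se > 2  # biased away from 0
    assert abs(endo.treatment_coefficient) < 2 * endo.treatment_se
    assert abs(endo.rho - 0.5) < 2 * endo.rho_se


def test_two_step_control_function_variant():
    df, _ = ktp.simulate_transplant_table(20000, beta1=0.0, rho=0.5, seed=9)
    r = ktp.EndogenousTreatmentProbit(SPEC, method="two-step").fit(df).result_
    # the control-function term soaks up the endogeneity
    assert abs(r.treatment_coefficient) < 3 * r.treatment_se
    assert r.extra["control_function_p"] < 0.2


def test_estimates_invariant_to_row_order_and_rescaling():
    df, _ = ktp.simulate_transplant_table(5000, beta1=0.3, rho=0.3, seed=10)
    base = ktp.fit_treatment_probit(df, SPEC, "endogenous")
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    perm = ktp.fit_treatment_probit(shuffled, SPEC, "endogenous")
    assert perm.treatment_coefficient == pytest.approx(
        base.treatment_coefficient, abs=1e-4)
    scaled = df.copy()
    scaled["age"] = scaled["age"] / 10.0
    resc = ktp.fit_treatment_probit(scaled, SPEC, "endogenous")
    assert resc.ate == pytest.approx(base.ate, abs=1e-3)
    assert resc.params["y:age"] == pytest.approx(10 * base.params["y:age"], rel=0.02)


def test_zero_treatment_coefficient_gives_zero_ate():
    df, _ = ktp.simulate_transplant_table(20000, beta1=0.0, rho=0.0, seed=11)
    r = ktp.fit_treatment_probit(df, SPEC, "endogenous")
    assert abs(r.ate) < 2 * abs(r.treatment_se) * stats.norm.pdf(1.5)  # prob scale


def test_profile_ci_brackets_estimate_and_covers_interior():
    df, _ = ktp.simulate_transplant_table(4000, beta1=0.3, rho=0.0, seed=12)
    est = ktp.EndogenousTreatmentProbit(SPEC).fit(df)
    lo, hi = est.profile_ci("treatment", span=3.0, tol=0.05)
    b1 = est.result_.treatment_coefficient
    assert lo <= b1 <= hi
    assert est.profile_ci_contains(b1)
    assert est.profile_ci_contains(0.5 * (lo + hi))
    assert not est.profile_ci_contains(hi + 2.0)
    # profile at the MLE reproduces the maximized log-likelihood
    assert est.profile_loglike(b1) == pytest.approx(
        est.result_.log_likelihood, abs=1e-3)


# --- market-share instrument ----------------------------------------------

def test_iv_single_program_dsa_is_one():
    tx = pd.DataFrame({
        "txp_id": ["A"] * 6, "dsa_id": ["D"] * 6,
        "transplant_date": pd.to_datetime(
            ["2015-01-05", "2015-02-05", "2015-03-05", "2015-04-05",
             "2015-05-05", "2015-06-05"])})
    iv = ktp.compute_iv(tx)
    assert (iv["iv_value"] == 1.0).all()


def test_iv_count_ratio():
    tx = pd.DataFrame({
        "txp_id": ["A", "A", "A", "B"], "dsa_id": ["D"] * 4,
        "transplant_date": pd.to_datetime(
            ["2015-01-10", "2015-02-10", "2015-03-05", "2015-02-20"])})
    iv = ktp.compute_iv(tx).set_index(["txp_id", "month"])
    m = pd.Period("2015-04")
    assert iv.loc[("A", m), "iv_value"] == 0.75
    assert iv.loc[("B", m), "iv_value"] == 0.25


def test_iv_undefined_for_empty_window_and_missing_dsa():
    tx = pd.DataFrame({
        "txp_id": ["A", "B"], "dsa_id": ["D", None],
        "transplant_date": pd.to_datetime(["2015-06-10", "2015-06-11"])})
    with pytest.warns(UserWarning, match="without DSA"):
        iv = ktp.compute_iv(tx)
    # months before any prior transplant have no defined value
    assert pd.Period("2015-06") not in set(iv["month"])
    assert (iv["iv_value"] >= 0).all() and (iv["iv_value"] <= 1).all()


def _iv_dgp(n=6000, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    iv = rng.uniform(0, 1, n)
    t = (1.5 * iv + 0.3 * x + rng.normal(size=n) > 1.2).astype(int)
    y = (0.3 + effect * t + 0.4 * x + rng.normal(size=n) > 0).astype(int)
    return pd.DataFrame({"survival_1yr": y, "tp": t, "iv_value": iv, "x": x})


def test_iv_two_step_null_effect_recovery():
    df = _iv_dgp(effect=0.0, seed=1)
    spec = ktp.ModelSpec(outcome="survival_1yr", treatment="tp",
                         step1_covariates=["iv_value"], controls=["x"])
    fit = ktp.TwoStepIVProbit(spec, n_bootstrap=60).fit(df)
    r = fit.result_
    assert not fit.weak_instrument_
    assert abs(r.treatment_coefficient) < 2 * r.treatment_se
    # exclusion diagnostic: instrument does not move the outcome directly
    assert r.extra["exclusion_p"] > 0.01


def test_iv_bootstrap_se_reflects_generated_regressor():
    """On average the bootstrap SE exceeds the naive step-2 SE, which ignores
    step-1 estimation error (per-sample the gap can flip sign)."""
    spec = ktp.ModelSpec(outcome="survival_1yr", treatment="tp",
                         step1_covariates=["iv_value"], controls=["x"])
    boot, naive = [], []
    for seed in (1, 2, 3):
        r = ktp.TwoStepIVProbit(spec, n_bootstrap=200).fit(
            _iv_dgp(n=2000, effect=0.0, seed=seed)).result_
        boot.append(r.treatment_se)
        naive.append(r.extra["naive_se"])
    assert np.mean(boot) > np.mean(naive)


def test_iv_weak_instrument_warning():
    df = _iv_dgp(seed=2)
    df["iv_value"] = np.random.default_rng(3).uniform(0, 1, len(df))  # pure noise
    spec = ktp.ModelSpec(outcome="survival_1yr", treatment="tp",
                         step1_covariates=["iv_value"], controls=["x"])
    with pytest.warns(UserWarning, match="weak instrument"):
        fit = ktp.TwoStepIVProbit(spec, n_bootstrap=5).fit(df)
    assert fit.weak_instrument_
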