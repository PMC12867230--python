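"""Probit machinery for the survival analysis.

Three estimators, all sklearn-style (``fit``/``get_params``/``set_params``,
fitted attributes with a trailing underscore), operating on a DataFrame with
named outcome / treatment / covariate columns:

* :class:`ProbitModel` — single-equation maximum-likelihood probit
  (statsmodels backend).
* :class:`EndogenousTreatmentProbit` — the two-equation treatment-effects
  model: a threshold-crossing treatment equation
  ``T = 1[alpha' z + xi > 0]`` and an outcome equation
  ``Y = 1[x' beta + beta1 T + eps > 0]`` with ``(xi, eps)`` bivariate normal,
  correlation ``rho``.  Estimated by full-information maximum likelihood
  (FIML) with analytic gradient through the bivariate-normal CDF; a
  two-step control-function variant is available.  At ``rho = 0`` the joint
  log-likelihood factorizes into the two separate probits.
* :class:`TwoStepIVProbit` — market-share instrument: step-1 probit of the
  treatment on the instrument, step-2 probit of the outcome on the predicted
  treatment probability plus controls, bootstrap standard errors for the
  generated regressor, plus relevance and exclusion diagnostics.

The average treatment effect (ATE) is always reported on the probability
scale: the sample mean of ``Phi(x'b + b1) - Phi(x'b)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.discrete.discrete_model import Probit
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .bvn import bvn_cdf, bvn_pdf

_PHI = stats.norm.cdf
_phi = stats.norm.pdf

#: bound on |rho| via rho = _RHO_MAX * tanh(arho); keeps the correlation
#: strictly inside the bivariate-normal CDF's numerical domain so the
#: analytic gradient stays consistent with the likelihood at the boundary
_RHO_MAX = 0.9999


def _rho_of(arho):
    return _RHO_MAX * np.tanh(arho)


def _drho_darho(arho):
    t = np.tanh(arho)
    return _RHO_MAX * (1.0 - t * t)


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class ModelSpec:
    """Column roles for the two-equation model."""

    outcome: str
    treatment: str
    step1_covariates: Sequence[str]
    controls: Sequence[str] = ()

    def __post_init__(self):
        if self.treatment in self.controls:
            raise ValueError("treatment must not appear among controls")


@dataclasses.dataclass
class FitResult:
    """Coefficients, standard errors and summary quantities of one fit."""

    params: pd.Series
    bse: pd.Series
    treatment_coefficient: Optional[float]
    treatment_se: Optional[float]
    ate: Optional[float]
    rho: Optional[float]
    rho_se: Optional[float]
    log_likelihood: float
    n_obs: int
    converged: bool = True
    extra: dict = dataclasses.field(default_factory=dict)

    @property
    def treatment_z(self) -> Optional[float]:
        if self.treatment_coefficient is None or not self.treatment_se:
            return None
        return self.treatment_coefficient / self.treatment_se

    @property
    def treatment_p(self) -> Optional[float]:
        z = self.treatment_z
        return None if z is None else float(2 * stats.norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "treatment_coefficient": self.treatment_coefficient,
            "treatment_se": self.treatment_se,
            "ate": self.ate,
            "rho": self.rho,
            "rho_se": self.rho_se,
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "converged": self.converged,
            **{k: v for k, v in self.extra.items() if np.isscalar(v) or v is None},
        }


def _design(data: pd.DataFrame, columns: Sequence[str], add_const: bool = True,
            prune: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix with dummy-coded categoricals (reference level = most
    frequent category) and a constant; collinear columns dropped with a
    warning unless ``prune`` is off (prediction re-uses the fitted names)."""
    parts, names = [], []
    if add_const:
        parts.append(np.ones((len(data), 1)))
        names.append("const")
    for col in columns:
        s = data[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            ref = s.mode().iloc[0]
            for level in sorted(set(s.dropna()) - {ref}, key=str):
                parts.append((s == level).to_numpy(float).reshape(-1, 1))
                names.append(f"{col}[{level}]")
        else:
            parts.append(s.to_numpy(float).reshape(-1, 1))
            names.append(col)
    X = np.hstack(parts)
    if not prune:
        return X, names
    # drop rank-deficient columns, keeping earlier ones
    keep = []
    for j in range(X.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear columns: {dropped}")
    return X[:, keep], [names[j] for j in keep]


class ProbitModel:
    """Single-equation ML probit over named DataFrame columns."""

    def __init__(self, outcome: str, covariates: Sequence[str] = (), add_const: bool = True):
        self.outcome = outcome
        self.covariates = list(covariates)
        self.add_const = add_const

    def get_params(self, deep=True):
        return {"outcome": self.outcome, "covariates": self.covariates,
                "add_const": self.add_const}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame, y=None) -> "ProbitModel":
        y_arr = data[self.outcome].to_numpy(float)
        if not np.isin(y_arr, [0.0, 1.0]).all():
            raise ValueError(f"outcome {self.outcome!r} must be binary 0/1")
        X, names = _design(data, self.covariates, self.add_const)
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = Probit(y_arr, X).fit(disp=0, maxiter=200)
            except (PerfectSeparationWarning, Exception) as exc:
                if "erfect" in str(type(exc).__name__) or "erfect" in str(exc):
                    raise ConvergenceError(f"perfect separation in probit: {exc}") from exc
                raise
        self.names_ = names
        self.params_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.bse, index=names)
        self.llf_ = float(res.llf)
        self.n_obs_ = int(res.nobs)
        self._sm_result = res
        self.result_ = FitResult(self.params_, self.bse_, None, None, None, None, None,
                                 self.llf_, self.n_obs_, converged=res.mle_retvals.get(
                                     "converged", True) if hasattr(res, "mle_retvals") else True)
        return self

    def predict_proba(self, data: pd.DataFrame, overrides: Optional[dict] = None) -> np.ndarray:
        """Predicted success probability; ``overrides`` substitutes covariate
        columns (arrays or scalars) before prediction."""
        df = data
        if overrides:
            df = data.copy()
            for k, v in overrides.items():
                df[k] = v
        X, names = _design(df, self.covariates, self.add_const, prune=False)
        cols = pd.DataFrame(X, columns=names)
        missing = [n for n in self.names_ if n not in cols.columns]
        if missing:
            raise ValueError(f"prediction data lacks fitted design columns {missing}")
        params = self.params_.to_numpy()
        return _PHI(cols[self.names_].to_numpy() @ params)


def fit_probit(data: pd.DataFrame, outcome: str, covariates: Sequence[str]) -> FitResult:
    return ProbitModel(outcome, covariates).fit(data).result_


class EndogenousTreatmentProbit:
    """Probit outcome model with a binary endogenous treatment.

    ``mode='endogenous'`` (default) estimates the joint FIML model; the
    per-observation likelihood is ``Phi2(q1 * x'b, q2 * z'a, q1 q2 rho)``
    with ``q = 2*indicator - 1``, maximized over ``(b, a, atanh(rho))``.
    ``mode='exogenous'`` is a single probit of the outcome on the actual
    treatment plus controls.  ``method='two-step'`` is the control-function
    variant: step-1 probit generalized residual appended to the outcome
    probit (its coefficient estimates ``rho`` up to scale).
    """

    def __init__(self, spec: ModelSpec, mode: str = "endogenous",
                 method: str = "fiml"):
        self.spec = spec
        self.mode = mode
        self.method = method

    def get_params(self, deep=True):
        return {"spec": self.spec, "mode": self.mode, "method": self.method}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # --- likelihood -------------------------------------------------------
    def _loglike_obs(self, theta, X, Z, y, t):
        kx, kz = X.shape[1] + 1, Z.shape[1]
        b = theta[:kx - 1]
        b1 = theta[kx - 1]
        a = theta[kx:kx + kz]
        rho = _rho_of(theta[-1])
        q1 = 2.0 * y - 1.0
        q2 = 2.0 * t - 1.0
        xb = X @ b + b1 * t
        za = Z @ a
        p = bvn_cdf(q1 * xb, q2 * za, q1 * q2 * rho)
        return np.log(np.clip(p, 1e-300, 1.0))

    def _score_obs(self, theta, X, Z, y, t):
        """Per-observation score matrix (n x n_params)."""
        kx, kz = X.shape[1] + 1, Z.shape[1]
        b = theta[:kx - 1]
        b1 = theta[kx - 1]
        a = theta[kx:kx + kz]
        arho = theta[-1]
        rho = _rho_of(arho)
        q1 = 2.0 * y - 1.0
        q2 = 2.0 * t - 1.0
        w1 = q1 * (X @ b + b1 * t)
        w2 = q2 * (Z @ a)
        r = q1 * q2 * rho
        p = np.clip(bvn_cdf(w1, w2, r), 1e-300, 1.0)
        s = np.sqrt(np.clip(1.0 - r * r, 1e-12, 1.0))
        g1 = _phi(w1) * _PHI((w2 - r * w1) / s) / p     # d logL / d w1
        g2 = _phi(w2) * _PHI((w1 - r * w2) / s) / p
        gr = bvn_pdf(w1, w2, r) / p                     # d logL / d r
        return np.hstack([
            (g1 * q1)[:, None] * X,
            (g1 * q1 * t)[:, None],
            (g2 * q2)[:, None] * Z,
            (gr * q1 * q2 * _drho_darho(arho))[:, None],
        ])

    def _score(self, theta, X, Z, y, t):
        return self._score_obs(theta, X, Z, y, t).sum(axis=0)

    def fit(self, data: pd.DataFrame, y=None) -> "EndogenousTreatmentProbit":
        spec = self.spec
        y_arr = data[spec.outcome].to_numpy(float)
        t_arr = data[spec.treatment].to_numpy(float)
        if not np.isin(t_arr, [0.0, 1.0]).all():
            raise ValueError("treatment must be binary")

        if self.mode == "exogenous":
            cols = [spec.treatment] + list(spec.controls)
            m = ProbitModel(spec.outcome, cols).fit(data)
            ate = self._ate_from_probit(m, data)
            self.result_ = FitResult(
                m.params_, m.bse_, float(m.params_[spec.treatment]),
                float(m.bse_[spec.treatment]), ate, None, None, m.llf_, m.n_obs_)
            self.outcome_model_ = m
            return self

        X, xnames = _design(data, list(spec.controls))
        Z, znames = _design(data, list(spec.step1_covariates))

        # start values: two separate probits; multi-start over the error
        # correlation (the joint likelihood can carry a flat (beta1, rho)
        # ridge, so a single start is not trusted)
        p_t = Probit(t_arr, Z).fit(disp=0, maxiter=200)
        p_y = Probit(y_arr, np.hstack([X, t_arr[:, None]])).fit(disp=0, maxiter=200)

        if self.method == "two-step":
            return self._fit_two_step(data, X, xnames, Z, znames, y_arr, t_arr, p_t)

        def nll(theta):
            return -self._loglike_obs(theta, X, Z, y_arr, t_arr).sum()

        def ngrad(theta):
            return -self._score(theta, X, Z, y_arr, t_arr)

        opt = None
        for arho0 in (-0.8, 0.0, 0.8):
            b0 = np.concatenate([p_y.params[:-1], [p_y.params[-1]], p_t.params, [arho0]])
            o = optimize.minimize(nll, b0, jac=ngrad, method="BFGS",
                                  options={"maxiter": 500, "gtol": 1e-5})
            if opt is None or o.fun < opt.fun:
                opt = o
        if not opt.success and np.linalg.norm(ngrad(opt.x)) > 1e-2 * max(1, len(y_arr) / 1000):
            raise ConvergenceError(
                f"FIML did not converge: {opt.message}; |grad| = "
                f"{np.linalg.norm(ngrad(opt.x)):.3g}")
        theta = opt.x
        hess = approx_hess1(theta, nll)
        try:
            vcov = np.linalg.inv(hess)
            diag = np.diag(vcov)
        except np.linalg.LinAlgError:
            diag = np.full(len(theta), -1.0)
        if (diag <= 0).any():
            # non-PD observed information (boundary / ridge): fall back to the
            # outer product of per-observation scores
            warnings.warn("observed information not positive definite; "
                          "using OPG standard errors")
            G = self._score_obs(theta, X, Z, y_arr, t_arr)
            vcov = np.linalg.pinv(G.T @ G)
            diag = np.diag(vcov)
        se = np.sqrt(np.clip(diag, 0.0, np.inf))

        kx = X.shape[1]
        names = ([f"y:{n}" for n in xnames] + [f"y:{spec.treatment}"]
                 + [f"t:{n}" for n in znames] + ["atanh_rho"])
        rho = float(_rho_of(theta[-1]))
        rho_se = float(se[-1] * _drho_darho(theta[-1]))
        if abs(rho) > 0.999:
            warnings.warn("rho estimate at the boundary; interpret with care")
        b = theta[:kx]
        b1 = float(theta[kx])
        xb = X @ b
        ate = float(np.mean(_PHI(xb + b1) - _PHI(xb)))
        params = pd.Series(theta, index=names)
        bses = pd.Series(se, index=names)
        wald_rho = (theta[-1] / se[-1]) ** 2 if se[-1] > 0 else np.inf
        self.result_ = FitResult(
            params, bses, b1, float(se[kx]), ate, rho, rho_se,
            float(-opt.fun), len(y_arr), converged=bool(opt.success),
            extra={"rho_wald_p": float(stats.chi2.sf(wald_rho, 1)),
                   "xnames": xnames, "znames": znames})
        self._X, self._Z, self._y, self._t = X, Z, y_arr, t_arr
        self.theta_ = theta
        self._b1_index = kx
        return self

    # --- profile likelihood ----------------------------------------------
    def profile_loglike(self, value: float, param: str = "treatment") -> float:
        """Log-likelihood maximized over all parameters except the fixed one.

        ``param`` is ``"treatment"`` (the treatment coefficient) or ``"rho"``
        (profiled on the atanh scale).  The joint likelihood can carry a flat
        treatment/correlation ridge that makes Wald intervals unreliable;
        likelihood-ratio inversion of this profile is the trustworthy
        interval construction for this model.
        """
        if not hasattr(self, "theta_"):
            raise AttributeError("fit the model first")
        X, Z, y, t = self._X, self._Z, self._y, self._t
        idx = self._b1_index if param == "treatment" else len(self.theta_) - 1
        fixed = (np.arctanh(np.clip(value / _RHO_MAX, -0.999999, 0.999999))
                 if param == "rho" else value)
        free = [i for i in range(len(self.theta_)) if i != idx]

        def pack(f):
            th = self.theta_.copy()
            th[free] = f
            th[idx] = fixed
            return th

        starts = []
        for off in (-1.0, 0.0, 1.0):
            f0 = self.theta_[free].copy()
            if param == "treatment":
                f0[-1] = 0.8 * off           # vary the correlation start
            else:
                f0[self._b1_index] += off    # vary the treatment-coefficient start
            starts.append(f0)
        best = None
        for f0 in starts:
            o = optimize.minimize(
                lambda f: -self._loglike_obs(pack(f), X, Z, y, t).sum(), f0,
                jac=lambda f: -self._score(pack(f), X, Z, y, t)[free],
                method="BFGS", options={"maxiter": 300})
            if best is None or o.fun < best.fun:
                best = o
        return float(-best.fun)

    def profile_ci_contains(self, value: float, param: str = "treatment",
                            level: float = 0.95) -> bool:
        """Whether the profile-likelihood-ratio CI at ``level`` contains
        ``value`` (the CI is defined by LR inversion, so membership needs a
        single constrained fit)."""
        crit = stats.chi2.ppf(level, 1)
        lr = 2.0 * (self.result_.log_likelihood - self.profile_loglike(value, param))
        return bool(lr <= crit + 1e-9)

    def profile_ci(self, param: str = "treatment", level: float = 0.95,
                   span: float = 4.0, tol: float = 1e-2) -> tuple[float, float]:
        """Profile-likelihood CI by bisection on each side of the estimate."""
        center = (self.result_.treatment_coefficient if param == "treatment"
                  else self.result_.rho)
        crit = stats.chi2.ppf(level, 1)
        llmax = self.result_.log_likelihood

        def lr(v):
            return 2.0 * (llmax - self.profile_loglike(v, param))

        bounds = []
        for sign in (-1.0, 1.0):
            lo, hi = center, center + sign * span
            if param == "rho":
                hi = float(np.clip(hi, -0.999, 0.999))
            if lr(hi) <= crit:
                bounds.append(hi)
                continue
            while abs(hi - lo) > tol:
                mid = 0.5 * (lo + hi)
                if lr(mid) <= crit:
                    lo = mid
                else:
                    hi = mid
            bounds.append(0.5 * (lo + hi))
        return (min(bounds), max(bounds))

    def _fit_two_step(self, data, X, xnames, Z, znames, y_arr, t_arr, p_t):
        za = Z @ p_t.params
        q2 = 2.0 * t_arr - 1.0
        gen_resid = q2 * _phi(za) / np.clip(_PHI(q2 * za), 1e-12, 1.0)
        X2 = np.hstack([X, t_arr[:, None], gen_resid[:, None]])
        res = Probit(y_arr, X2).fit(disp=0, maxiter=200)
        names = [f"y:{n}" for n in xnames] + [f"y:{self.spec.treatment}", "y:gen_resid"]
        b1 = float(res.params[-2])
        xb = X @ res.params[:X.shape[1]]
        ate = float(np.mean(_PHI(xb + b1) - _PHI(xb)))
        self.result_ = FitResult(
            pd.Series(res.params, index=names), pd.Series(res.bse, index=names),
            b1, float(res.bse[-2]), ate, None, None, float(res.llf), len(y_arr),
            extra={"control_function_coef": float(res.params[-1]),
                   "control_function_p": float(res.pvalues[-1])})
        return self

    def _ate_from_probit(self, m: ProbitModel, data: pd.DataFrame) -> float:
        t = self.spec.treatment
        p1 = m.predict_proba(data, overrides={t: 1})
        p0 = m.predict_proba(data, overrides={t: 0})
        return float(np.mean(p1 - p0))


def fit_treatment_probit(data: pd.DataFrame, spec: ModelSpec,
                         mode: str = "endogenous") -> FitResult:
    return EndogenousTreatmentProbit(spec, mode=mode).fit(data).result_


# --- market-share instrument ---------------------------------------------

def compute_iv(transplants: pd.DataFrame, window_months: int = 3) -> pd.DataFrame:
    """Program market share: transplants by a program over the previous
    ``window_months`` calendar months divided by all transplants in its DSA
    over the same window; one value per (program, month).

    Months whose DSA window total is zero yield no row (the instrument is
    undefined there).  Rows lacking DSA information are dropped with a
    warning.  The caller is responsible for excluding the first
    ``window_months`` months of the data window from downstream fits.
    """
    req = {"txp_id", "dsa_id", "transplant_date"}
    missing_cols = req - set(transplants.columns)
    if missing_cols:
        raise ValueError(f"transplants table lacks {sorted(missing_cols)}")
    tx = transplants.copy()
    no_dsa = tx["dsa_id"].isna()
    if no_dsa.any():
        warnings.warn(f"dropping {int(no_dsa.sum())} transplants without DSA information")
        tx = tx.loc[~no_dsa]
    tx["month"] = pd.to_datetime(tx["transplant_date"]).dt.to_period("M")
    counts = tx.groupby(["dsa_id", "txp_id", "month"]).size().rename("n").reset_index()
    months = pd.period_range(tx["month"].min(), tx["month"].max() + 1, freq="M")
    rows = []
    for dsa, g in counts.groupby("dsa_id"):
        by_month = g.groupby("month")["n"].sum()
        for txp, gt in g.groupby("txp_id"):
            txp_by_month = gt.set_index("month")["n"]
            for m in months:
                window = [m - k for k in range(1, window_months + 1)]
                denom = sum(by_month.get(w, 0) for w in window)
                if denom == 0:
                    continue
                num = sum(txp_by_month.get(w, 0) for w in window)
                rows.append({"txp_id": txp, "dsa_id": dsa, "month": m,
                             "iv_value": num / denom})
    return pd.DataFrame(rows, columns=["txp_id", "dsa_id", "month", "iv_value"])


class TwoStepIVProbit:
    """Two-step probit with the market-share instrument.

    Step 1: probit of the treatment on the instrument (instrument-only by
    default; ``controls_in_step1`` adds the control set).  Step 2: probit of
    the outcome on the predicted treatment probability plus controls.
    Standard errors of step 2 come from a nonparametric bootstrap over
    observations (the generated-regressor problem).  Diagnostics: the
    relevance test (step-1 instrument z), the exclusion check (instrument
    coefficient in an outcome probit), and the correlation of the two
    equations' generalized residuals.
    """

    def __init__(self, spec: ModelSpec, iv_column: str = "iv_value",
                 controls_in_step1: bool = False, n_bootstrap: int = 100,
                 random_state: int = 0):
        self.spec = spec
        self.iv_column = iv_column
        self.controls_in_step1 = controls_in_step1
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"spec": self.spec, "iv_column": self.iv_column,
                "controls_in_step1": self.controls_in_step1,
                "n_bootstrap": self.n_bootstrap, "random_state": self.random_state}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _step_fits(self, data: pd.DataFrame):
        spec = self.spec
        s1_cols = [self.iv_column] + (list(spec.controls) if self.controls_in_step1 else [])
        step1 = ProbitModel(spec.treatment, s1_cols).fit(data)
        that = step1.predict_proba(data)
        d2 = data.copy()
        d2["_that"] = that
        step2 = ProbitModel(spec.outcome, ["_that"] + list(spec.controls)).fit(d2)
        return step1, step2

    def fit(self, data: pd.DataFrame, y=None) -> "TwoStepIVProbit":
        spec = self.spec
        step1, step2 = self._step_fits(data)
        iv_z = step1.params_[self.iv_column] / step1.bse_[self.iv_column]
        self.weak_instrument_ = bool(abs(iv_z) < 2)
        if self.weak_instrument_:
            warnings.warn(f"weak instrument: step-1 |z| = {abs(iv_z):.2f} < 2")

        # bootstrap step-2 SEs (generated regressor)
        rng = np.random.default_rng(self.random_state)
        boots = []
        n = len(data)
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, n, n)
            sample = data.iloc[idx]
            try:
                _, b2 = self._step_fits(sample)
                boots.append(b2.params_["_that"])
            except (ConvergenceError, np.linalg.LinAlgError):
                continue
        boot_se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan

        # exclusion check: instrument directly in the outcome equation
        excl = ProbitModel(spec.outcome, [self.iv_column] + list(spec.controls)).fit(data)
        excl_z = excl.params_[self.iv_column] / excl.bse_[self.iv_column]

        # error-correlation diagnostic via generalized residuals
        def gresid(m: ProbitModel, yv):
            xb = stats.norm.ppf(np.clip(m.predict_proba(data), 1e-10, 1 - 1e-10))
            q = 2 * yv - 1
            return q * _phi(xb) / np.clip(_PHI(q * xb), 1e-12, 1.0)

        g1 = gresid(step1, data[spec.treatment].to_numpy(float))
        d2 = data.copy()
        d2["_that"] = step1.predict_proba(data)
        xb2 = stats.norm.ppf(np.clip(step2.predict_proba(d2), 1e-10, 1 - 1e-10))
        q2 = 2 * data[spec.outcome].to_numpy(float) - 1
        g2 = q2 * _phi(xb2) / np.clip(_PHI(q2 * xb2), 1e-12, 1.0)
        rho_diag = float(np.corrcoef(g1, g2)[0, 1])

        b1 = float(step2.params_["_that"])
        ate = float(np.mean(step2.predict_proba(d2, overrides={"_that": 1.0})
                            - step2.predict_proba(d2, overrides={"_that": 0.0})))

        self.step1_ = step1.result_
        self.step2_ = step2.result_
        self.result_ = FitResult(
            step2.params_, step2.bse_, b1, boot_se, ate, rho_diag, None,
            step2.llf_, step2.n_obs_,
            extra={"iv_coefficient": float(step1.params_[self.iv_column]),
                   "iv_se": float(step1.bse_[self.iv_column]),
                   "iv_relevance_z": float(iv_z),
                   "exclusion_z": float(excl_z),
                   "exclusion_p": float(2 * stats.norm.sf(abs(excl_z))),
                   "weak_instrument": self.weak_instrument_,
                   "naive_se": float(step2.bse_["_that"])})
        return self


def fit_iv_probit(data: pd.DataFrame, spec: ModelSpec, iv: pd.DataFrame,
                  iv_column: str = "iv_value", **kwargs) -> FitResult:
    """Join the instrument series on (txp_id, month) and fit the two-step
    model.  Observations without an instrument value are dropped."""
    d = data.copy()
    d["month"] = pd.to_datetime(d["transplant_date"]).dt.to_period("M")
    d = d.merge(iv[["txp_id", "month", "iv_value"]], on=["txp_id", "month"], how="left")
    d = d.loc[d["iv_value"].notna()].reset_index(drop=True)
    return TwoStepIVProbit(spec, iv_column=iv_column, **kwargs).fit(d).result_
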