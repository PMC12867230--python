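"""Double machine learning for the partially linear and partially linear IV
models with K-fold cross-fitting.

Partially linear model:  ``Y = theta0 * P + g0(X) + U``, ``P = m0(X) + V``.
The nuisance conditional means are fit on the out-of-fold complement and the
treatment effect solves the Robinson residual-on-residual (partialling-out)
moment pooled across folds:

    theta_hat = sum(V_hat * (Y - l_hat)) / sum(V_hat^2),

with the standard error from the influence function
``psi = V_hat * (Y - l_hat - theta * V_hat)``.  The IV variant residualizes
the outcome, the treatment and the (single continuous) instrument on X and
solves the residualized IV moment.  A binary outcome is treated on the
linear-probability scale, as the partially linear model prescribes — the
coefficient is itself the average treatment effect.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

LEARNERS = ("gbm", "rf", "linear")


class WeakInstrumentError(RuntimeError):
    pass


@dataclasses.dataclass
class DMLResult:
    theta_hat: float
    se: float
    fold_thetas: list[float]
    n_obs: int
    n_folds: int
    nuisance_r2: dict = dataclasses.field(default_factory=dict)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.theta_hat - 1.96 * self.se, self.theta_hat + 1.96 * self.se)

    def to_dict(self) -> dict:
        return {"theta_hat": self.theta_hat, "se": self.se,
                "fold_thetas": self.fold_thetas, "n_obs": self.n_obs,
                "n_folds": self.n_folds}


def _make_learner(name: str, seed: int):
    if name == "gbm":
        return GradientBoostingRegressor(n_estimators=100, max_depth=3,
                                         learning_rate=0.1, random_state=seed)
    if name == "rf":
        return RandomForestRegressor(n_estimators=200, min_samples_leaf=5,
                                     random_state=seed)
    if name == "linear":
        return Ridge(alpha=1.0)
    raise ValueError(f"unknown learner {name!r}; choose from {LEARNERS}")


class _BaseDML:
    def __init__(self, n_folds: int = 4, learner: str = "gbm", random_state: int = 0):
        self.n_folds = n_folds
        self.learner = learner
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"n_folds": self.n_folds, "learner": self.learner,
                "random_state": self.random_state}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _crossfit_residuals(self, X, targets: dict[str, np.ndarray]):
        """Out-of-fold residuals for each named target regressed on X."""
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.random_state)
        resid = {k: np.empty_like(v, dtype=float) for k, v in targets.items()}
        folds = list(kf.split(X))
        for train, test in folds:
            for k, v in targets.items():
                model = _make_learner(self.learner, self.random_state)
                model.fit(X[train], v[train])
                resid[k][test] = v[test] - model.predict(X[test])
        return resid, folds


class DMLPartiallyLinear(_BaseDML):
    """Cross-fit partialling-out estimator of the partially linear model."""

    def fit(self, X, y, treatment) -> "DMLPartiallyLinear":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        d = np.asarray(treatment, float)
        resid, folds = self._crossfit_residuals(X, {"y": y, "d": d})
        vy, vd = resid["y"], resid["d"]
        fold_thetas = []
        for train, test in folds:
            denom = np.sum(vd[test] ** 2)
            if denom < 1e-12:
                raise RuntimeError(
                    "a fold has (near-)constant residualized treatment; re-split "
                    "with a different seed")
            fold_thetas.append(float(np.sum(vd[test] * vy[test]) / denom))
        theta = float(np.sum(vd * vy) / np.sum(vd ** 2))
        n = len(y)
        psi = vd * (vy - theta * vd)
        j = np.mean(vd ** 2)
        se = float(np.sqrt(np.mean(psi ** 2) / n) / j)
        self.result_ = DMLResult(theta, se, fold_thetas, n, self.n_folds,
                                 {"var_resid_treatment": float(np.var(vd))})
        self.theta_ = theta
        self.se_ = se
        return self


class DMLPartiallyLinearIV(_BaseDML):
    """Cross-fit partially linear IV: residualized-instrument moment."""

    def fit(self, X, y, treatment, instrument) -> "DMLPartiallyLinearIV":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        d = np.asarray(treatment, float)
        z = np.asarray(instrument, float)
        resid, folds = self._crossfit_residuals(X, {"y": y, "d": d, "z": z})
        vy, vd, vz = resid["y"], resid["d"], resid["z"]
        cov_zd = np.mean(vz * vd)
        # weak iff the first-stage covariance is indistinguishable from zero
        cov_se = np.sqrt(np.var(vz * vd) / len(vd))
        if cov_se < 1e-12 or abs(cov_zd) < 3.0 * cov_se:
            raise WeakInstrumentError(
                f"residualized instrument-treatment covariance {cov_zd:.3g} "
                f"(se {cov_se:.3g}) is indistinguishable from zero; the "
                "instrument carries no identifying variation")
        fold_thetas = []
        for train, test in folds:
            c = np.sum(vz[test] * vd[test])
            if abs(c) > 1e-12:
                fold_thetas.append(float(np.sum(vz[test] * vy[test]) / c))
        theta = float(np.sum(vz * vy) / np.sum(vz * vd))
        n = len(y)
        psi = vz * (vy - theta * vd)
        j = cov_zd
        se = float(np.sqrt(np.mean(psi ** 2) / n) / abs(j))
        self.result_ = DMLResult(theta, se, fold_thetas, n, self.n_folds,
                                 {"cov_resid_zd": float(cov_zd)})
        self.theta_ = theta
        self.se_ = se
        return self


def crossfit_plm(data: pd.DataFrame, outcome: str, treatment: str,
                 controls: Sequence[str], n_folds: int = 4, learner: str = "gbm",
                 random_state: int = 0) -> DMLResult:
    if not controls:
        raise ValueError("controls must be nonempty")
    est = DMLPartiallyLinear(n_folds=n_folds, learner=learner, random_state=random_state)
    est.fit(data[list(controls)].to_numpy(float), data[outcome].to_numpy(float),
            data[treatment].to_numpy(float))
    return est.result_


def crossfit_plm_iv(data: pd.DataFrame, outcome: str, treatment: str, iv: str,
                    controls: Sequence[str], n_folds: int = 4, learner: str = "gbm",
                    random_state: int = 0) -> DMLResult:
    if not controls:
        raise ValueError("controls must be nonempty")
    est = DMLPartiallyLinearIV(n_folds=n_folds, learner=learner, random_state=random_state)
    est.fit(data[list(controls)].to_numpy(float), data[outcome].to_numpy(float),
            data[treatment].to_numpy(float), data[iv].to_numpy(float))
    return est.result_
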