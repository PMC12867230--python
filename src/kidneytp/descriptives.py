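"""Group-comparison statistics: normality-gated location tests, chi-square
with Cramér's V, empirical-CDF stochastic dominance, and temporal trend
tests of the targeted-placement rate.

Continuous variables are compared with Welch's unequal-variance t-test when
both samples pass the skewness-kurtosis (D'Agostino-Pearson omnibus)
normality test at the 5% level, and otherwise with the Mann-Whitney U test,
reported with its normal-approximation z statistic (tie and continuity
corrected).  Categorical variables are compared with Pearson's chi-square
and effect size Cramér's V = sqrt(chi2 / (n * (min(r, c) - 1))).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

NORMALITY_ALPHA = 0.05
#: minimum per-sample size for the normality gate (kurtosis test validity)
MIN_N = 8


@dataclasses.dataclass
class ComparisonResult:
    variable: str
    test: str                       # welch_t | mann_whitney_u | chi_square
    statistic: float
    p_value: float
    group_stats: dict
    effect_size: Optional[float] = None   # Cramér's V for categorical
    normality_p: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        if self.effect_size is not None and not 0.0 <= self.effect_size <= 1.0 + 1e-12:
            raise ValueError(f"Cramér's V out of [0,1]: {self.effect_size}")


def mann_whitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U statistic, z (tie- and continuity-corrected) and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 0.0, 1.0
    # continuity correction toward the null
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return u1, float(z), float(min(p, 1.0))


def compare_continuous(x, y, variable: str = "", groups: tuple[str, str] = ("a", "b")
                       ) -> ComparisonResult:
    """Welch t if both samples pass the normality gate, else Mann-Whitney U."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < MIN_N or len(y) < MIN_N:
        raise ValueError(
            f"normality gate needs n >= {MIN_N} per sample, got {len(x)}, {len(y)}")
    px = stats.normaltest(x).pvalue
    py = stats.normaltest(y).pvalue
    gs = {groups[0]: {"n": len(x), "mean": float(np.mean(x)), "median": float(np.median(x))},
          groups[1]: {"n": len(y), "mean": float(np.mean(y)), "median": float(np.median(y))}}
    if px > NORMALITY_ALPHA and py > NORMALITY_ALPHA:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return ComparisonResult(variable, "welch_t", float(t), float(p), gs,
                                normality_p=(float(px), float(py)))
    _, z, p = mann_whitney_z(x, y)
    return ComparisonResult(variable, "mann_whitney_u", z, p, gs,
                            normality_p=(float(px), float(py)))


def compare_categorical(table, variable: str = "") -> ComparisonResult:
    """Pearson chi-square with Cramér's V on a contingency table of counts."""
    tab = np.asarray(table, float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    n = tab.sum()
    v = float(np.sqrt(chi2 / (n * (min(tab.shape) - 1))))
    gs = {"shape": tab.shape, "n": int(n)}
    return ComparisonResult(variable, "chi_square", float(chi2), float(p), gs,
                            effect_size=v)


def ecdf_dominance(x, y) -> str:
    """Stochastic-dominance verdict from the two empirical CDFs.

    Evaluates both eCDFs on the pooled support.  Returns ``"x<=y"`` when the
    eCDF of y lies (weakly) below that of x everywhere — i.e. y is
    stochastically larger — ``"y<=x"`` for the symmetric case, ``"equal"``
    when both hold, ``"neither"`` when the eCDFs cross.
    """
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be nonempty")
    grid = np.union1d(x, y)
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    x_le_y = bool((fy <= fx).all())
    y_le_x = bool((fx <= fy).all())
    if x_le_y and y_le_x:
        return "equal"
    if x_le_y:
        return "x<=y"
    if y_le_x:
        return "y<=x"
    return "neither"


def temporal_trend_test(labels: pd.DataFrame, stratum: str = "hour",
                        time_column: str = "accept_time") -> ComparisonResult:
    """Chi-square homogeneity of the TP proportion across time strata.

    ``stratum`` is one of ``hour`` (of day), ``weekday``, ``month`` (calendar
    year-month).  The clock defaults to the recipient's initial-response
    (acceptance) timestamp, which exists for targeted and non-targeted
    transplants alike; rows without it are dropped.  Strata with zero
    transplants are dropped.
    """
    t = pd.to_datetime(labels[time_column])
    ok = t.notna()
    t, is_tp = t[ok], labels.loc[ok, "is_tp"].astype(bool)
    if stratum == "hour":
        key = t.dt.hour
    elif stratum == "weekday":
        key = t.dt.dayofweek
    elif stratum == "month":
        key = t.dt.to_period("M").astype(str)
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    tab = pd.crosstab(key, is_tp)
    tab = tab.loc[tab.sum(axis=1) > 0]
    if tab.shape[0] < 2:
        raise ValueError("need at least two nonempty strata for a trend test")
    if tab.shape[1] < 2:
        # all-TP or all-NTP: homogeneity trivially not rejected
        return ComparisonResult(f"tp_rate_by_{stratum}", "chi_square", 0.0, 1.0,
                                {"n_strata": tab.shape[0]}, effect_size=0.0)
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    v = float(np.sqrt(chi2 / (tab.to_numpy().sum() * (min(tab.shape) - 1))))
    return ComparisonResult(f"tp_rate_by_{stratum}", "chi_square", float(chi2),
                            float(p), {"n_strata": tab.shape[0]}, effect_size=v)


def share(count: int, total: int, decimals: int = 1) -> float:
    """Percentage as printed in reports: round-half-away-from-zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    q = 10 ** decimals
    return float(np.floor(pct * q + 0.5) / q)


def cohort_summary(classes: dict, cohort, labels: pd.DataFrame) -> pd.DataFrame:
    """Covariate comparison tables: TP vs NTP donors and recipients, BTD vs
    non-BTD candidates.  One row per (population, variable) with the test
    used, statistic, p-value and group means/sizes."""
    rows = []

    def add(population, variable, result: ComparisonResult):
        rec = {"population": population, "variable": variable, "test": result.test,
               "statistic": result.statistic, "p_value": result.p_value,
               "effect_size": result.effect_size}
        for g, s in result.group_stats.items():
            if isinstance(s, dict):
                rec[f"mean_{g}"] = s.get("mean")
                rec[f"n_{g}"] = s.get("n")
        rows.append(rec)

    donors = cohort.donors.merge(classes["donors"], on="donor_id")
    donors = donors.loc[donors["transplanted"]]
    tp_d, ntp_d = donors.loc[donors["tp_donor"]], donors.loc[~donors["tp_donor"]]
    if len(tp_d) >= MIN_N and len(ntp_d) >= MIN_N:
        for var in ("kdpi", "age", "creatinine"):
            add("donors", var, compare_continuous(ntp_d[var], tp_d[var], var, ("ntp", "tp")))
        tab = pd.crosstab(donors["tp_donor"], donors["race"])
        if tab.shape[0] == 2 and tab.shape[1] >= 2:
            add("donors", "race", compare_categorical(tab.to_numpy(), "race"))
        tab = pd.crosstab(donors["tp_donor"], donors["diabetes"])
        if tab.shape == (2, 2):
            add("donors", "diabetes", compare_categorical(tab.to_numpy(), "diabetes"))

    rec = classes["recipients"].merge(cohort.candidates, on="ptr_id", how="left")
    rec = rec.merge(
        cohort.transplants[["ptr_id", "time_to_transplant", "survival_1yr"]],
        on="ptr_id", how="left")
    tp_r, ntp_r = rec.loc[rec["tp_recipient"]], rec.loc[~rec["tp_recipient"]]
    if len(tp_r) >= MIN_N and len(ntp_r) >= MIN_N:
        for var in ("epts", "age_at_listing", "time_to_transplant"):
            add("recipients", var,
                compare_continuous(ntp_r[var], tp_r[var], var, ("ntp", "tp")))
        surv = pd.crosstab(rec["tp_recipient"], rec["survival_1yr"])
        if surv.shape == (2, 2):
            add("recipients", "survival_1yr",
                compare_categorical(surv.to_numpy(), "survival_1yr"))

    cand = classes["candidates"].merge(cohort.candidates, on="ptr_id")
    btd_c, non_c = cand.loc[cand["btd_candidate"]], cand.loc[~cand["btd_candidate"]]
    if len(btd_c) >= MIN_N and len(non_c) >= MIN_N:
        for var in ("age_at_listing", "epts"):
            add("candidates", var,
                compare_continuous(non_c[var], btd_c[var], var, ("non_btd", "btd")))
        tab = pd.crosstab(cand["btd_candidate"], cand["sex"])
        if tab.shape == (2, 2):
            add("candidates", "sex", compare_categorical(tab.to_numpy(), "sex"))

    return pd.DataFrame(rows)
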