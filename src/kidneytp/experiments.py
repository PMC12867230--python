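"""In-silico counterfactual experiments and the placebo test.

Three procedures probe the survival findings beyond the regression models:

* :func:`counterfactual_tp` — what if targeted recipients had instead waited
  like their non-targeted counterparts and received a similar-quality
  kidney?  A survival probit (without the treatment indicator) is fit on
  recipients; each targeted recipient is matched to non-targeted recipients
  at the same program, in the same EPTS vigintile, with longer waiting time;
  their average donor KDPI and waiting time are substituted into the fitted
  model and the predicted survival compared with the prediction at the
  recipient's own values.

* :func:`missed_opportunity_btd` — for recipients who were skipped in a
  batch turn down before their own transplant, predict the survival each
  earlier skipped offer would have delivered (substituting that donor's
  KDPI and the waiting time implied by the offer date) and count recipients
  with at least one offer predicted at least as good as the transplant they
  eventually received.  Lead time is reported in months of 30.44 days.

* :func:`placebo_test` — relabel a uniformly drawn pseudo-treatment group of
  the same size as the targeted group and refit the exogenous and endogenous
  treatment models; a sound pipeline finds no pseudo-effect.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labeling import BTDEvent
from .models import EndogenousTreatmentProbit, FitResult, ModelSpec, ProbitModel

DAYS_PER_MONTH = 30.44
EPTS_BINS = 20

#: default covariates of the recipient-level survival probits
SURVIVAL_COVARIATES = ("kdpi", "time_to_transplant", "age", "epts")


@dataclasses.dataclass
class CounterfactualTPResult:
    per_recipient: pd.DataFrame    # ptr_id, p_current, p_counterfactual, n_matches
    mean_current: float
    mean_counterfactual: float
    paired_p_value: float
    n_matched: int
    n_unmatched: int


@dataclasses.dataclass
class MissedOpportunityResult:
    n_btd_recipients: int
    n_with_dominating_offer: int
    mean_lead_time_months: float
    per_recipient: pd.DataFrame

    @property
    def rate(self) -> float:
        if self.n_btd_recipients == 0:
            return float("nan")
        return self.n_with_dominating_offer / self.n_btd_recipients

    def __post_init__(self):
        if self.n_with_dominating_offer > self.n_btd_recipients:
            raise ValueError("dominated count exceeds cohort size")


@dataclasses.dataclass
class PlaceboResult:
    replicates: list[dict]         # per replicate: seed, exogenous/endogenous FitResult
    n_pseudo: int

    def n_significant(self, which: str = "exogenous", alpha: float = 0.05) -> int:
        out = 0
        for rep in self.replicates:
            p = rep[which].treatment_p
            if p is not None and p < alpha:
                out += 1
        return out


def recipient_frame(cohort, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-transplant analysis rows: recipient covariates at transplant,
    donor KDPI, waiting time, survival and the TP label."""
    tx = cohort.transplants.merge(
        labels[["donor_id", "ptr_id", "is_tp", "rule_id", "batch_time"]],
        on=["donor_id", "ptr_id"], how="left")
    tx["is_tp"] = tx["is_tp"].fillna(False).astype(bool)
    tx = tx.merge(cohort.donors[["donor_id", "kdpi", "age"]].rename(
        columns={"age": "donor_age"}), on="donor_id", how="left")
    tx = tx.merge(cohort.candidates[["ptr_id", "dsa_id", "epts", "age_at_listing",
                                     "listing_date"]], on="ptr_id", how="left")
    tx["age"] = (tx["age_at_listing"]
                 + (tx["transplant_date"] - tx["listing_date"]).dt.days / 365.25)
    tx["tp"] = tx["is_tp"].astype(int)
    tx["survival_1yr"] = tx["survival_1yr"].astype("Int64").astype(float)
    return tx


def counterfactual_tp(
    frame: pd.DataFrame,
    covariates: Sequence[str] = SURVIVAL_COVARIATES,
    fit_on: str = "all",
) -> CounterfactualTPResult:
    """Matched substitution of KDPI and waiting time for targeted recipients.

    ``frame`` comes from :func:`recipient_frame`.  ``fit_on`` selects the
    recipients used to fit the survival probit (``"all"`` or ``"ntp"``).
    Targeted recipients without matches are excluded from the paired
    comparison and counted in ``n_unmatched``.
    """
    df = frame.dropna(subset=["survival_1yr", *covariates]).copy()
    fit_df = df if fit_on == "all" else df.loc[~df["is_tp"]]
    model = ProbitModel("survival_1yr", list(covariates)).fit(fit_df)

    # 20 equal-probability EPTS bins on the pooled recipient sample
    df["epts_bin"] = pd.qcut(df["epts"], EPTS_BINS, labels=False, duplicates="drop")

    tp = df.loc[df["is_tp"]]
    ntp = df.loc[~df["is_tp"]]
    rows = []
    for r in tp.itertuples(index=False):
        m = ntp.loc[(ntp["txp_id"] == r.txp_id)
                    & (ntp["epts_bin"] == r.epts_bin)
                    & (ntp["time_to_transplant"] > r.time_to_transplant)]
        rec = {"ptr_id": r.ptr_id, "n_matches": len(m),
               "p_current": np.nan, "p_counterfactual": np.nan}
        if len(m):
            own = pd.DataFrame([r._asdict()])
            rec["p_current"] = float(model.predict_proba(own)[0])
            rec["p_counterfactual"] = float(model.predict_proba(
                own, overrides={"kdpi": m["kdpi"].mean(),
                                "time_to_transplant": m["time_to_transplant"].mean()})[0])
        rows.append(rec)
    per = pd.DataFrame(rows, columns=["ptr_id", "n_matches", "p_current",
                                      "p_counterfactual"])
    matched = per.dropna(subset=["p_current", "p_counterfactual"])
    if len(matched) >= 2 and not np.allclose(matched["p_current"],
                                             matched["p_counterfactual"]):
        p = float(stats.ttest_rel(matched["p_current"], matched["p_counterfactual"]).pvalue)
    elif len(matched) >= 1:
        p = 1.0
    else:
        p = float("nan")
    return CounterfactualTPResult(
        per_recipient=per,
        mean_current=float(matched["p_current"].mean()) if len(matched) else float("nan"),
        mean_counterfactual=(float(matched["p_counterfactual"].mean())
                             if len(matched) else float("nan")),
        paired_p_value=p,
        n_matched=len(matched),
        n_unmatched=int(len(per) - len(matched)),
    )


def _offer_refusal_lookup(cohort) -> dict:
    off = cohort.offers
    return dict(zip(zip(off["match_run_id"], off["ptr_id"]), off["refusal_code"]))


def missed_opportunity_btd(
    cohort,
    frame: pd.DataFrame,
    events: Iterable[BTDEvent],
    covariates: Sequence[str] = SURVIVAL_COVARIATES,
    exclusion_mode: str = "none",
) -> MissedOpportunityResult:
    """Count skipped-then-transplanted recipients whose earlier skipped offers
    were predicted at least as good as their eventual transplant.

    A recipient enters the cohort if they were a batch member strictly before
    their own transplant.  Ties count ("at least as high").
    ``exclusion_mode='refusal_801_and_other'`` drops skipped offers declined
    for code 801 or a free-text/"other" reason before counting.
    """
    if exclusion_mode not in ("none", "refusal_801_and_other"):
        raise ValueError(f"unknown exclusion_mode {exclusion_mode!r}")
    df = frame.dropna(subset=["survival_1yr", *covariates]).copy()
    by_ptr = {r.ptr_id: r for r in df.itertuples(index=False)}
    donor_kdpi = dict(zip(cohort.donors["donor_id"], cohort.donors["kdpi"]))
    refusal = _offer_refusal_lookup(cohort) if exclusion_mode != "none" else {}

    # earlier skipped offers per transplanted recipient
    skipped: dict[str, list[BTDEvent]] = {}
    for e in events:
        for p in e.skipped_ptr_ids:
            r = by_ptr.get(p)
            if r is None or pd.isna(r.transplant_date):
                continue
            if e.batch_time >= r.transplant_date:
                continue
            if exclusion_mode == "refusal_801_and_other":
                rc = refusal.get((e.match_run_id, p))
                if rc is not None and (rc == "801" or not str(rc).isdigit()):
                    continue
            skipped.setdefault(p, []).append(e)

    btd_recipients = sorted(skipped)
    if not btd_recipients:
        return MissedOpportunityResult(0, 0, float("nan"),
                                       pd.DataFrame(columns=["ptr_id", "n_offers",
                                                             "dominating", "lead_months"]))
    model = ProbitModel("survival_1yr", list(covariates)).fit(
        df.loc[df["ptr_id"].isin(btd_recipients)])

    rows = []
    for p in btd_recipients:
        r = by_ptr[p]
        own = pd.DataFrame([r._asdict()])
        p_accepted = float(model.predict_proba(own)[0])
        best_lead = None
        dominating = False
        for e in skipped[p]:
            kdpi = donor_kdpi.get(e.donor_id)
            if kdpi is None or pd.isna(kdpi):
                continue
            wait_years = (e.batch_time.normalize() - r.listing_date).days / 365.25
            p_offer = float(model.predict_proba(
                own, overrides={"kdpi": kdpi,
                                "time_to_transplant": max(wait_years, 0.0)})[0])
            if p_offer >= p_accepted:
                dominating = True
                lead = (r.transplant_date - e.batch_time.normalize()).days / DAYS_PER_MONTH
                if best_lead is None or lead > best_lead:
                    best_lead = lead    # earliest dominating offer = longest lead
        rows.append({"ptr_id": p, "n_offers": len(skipped[p]),
                     "dominating": dominating,
                     "lead_months": best_lead if dominating else np.nan})
    per = pd.DataFrame(rows)
    dom = per.loc[per["dominating"]]
    return MissedOpportunityResult(
        n_btd_recipients=len(per),
        n_with_dominating_offer=int(per["dominating"].sum()),
        mean_lead_time_months=float(dom["lead_months"].mean()) if len(dom) else float("nan"),
        per_recipient=per,
    )


def placebo_test(
    frame: pd.DataFrame,
    spec: Optional[ModelSpec] = None,
    n_replicates: int = 5,
    seed: int = 0,
    modes: Sequence[str] = ("exogenous", "endogenous"),
) -> PlaceboResult:
    """Refit the treatment models on uniformly relabeled pseudo-treatments.

    Each replicate draws, without replacement, as many transplants as the
    true targeted count, labels them pseudo-treated, and refits the selected
    models.  Replicate RNGs are spawned from ``seed`` so permuting seeds
    permutes replicates.
    """
    spec = spec or ModelSpec(outcome="survival_1yr", treatment="pseudo_tp",
                             step1_covariates=["age", "kdpi", "epts"],
                             controls=["kdpi", "age", "epts"])
    df = frame.dropna(subset=["survival_1yr", "age", "kdpi", "epts"]).copy()
    n_tp = int(df["is_tp"].sum())
    if n_tp == 0:
        raise ValueError("no targeted transplants; placebo test undefined")
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    replicates = []
    for i, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        idx = rng.choice(len(df), size=n_tp, replace=False)
        d = df.copy()
        d["pseudo_tp"] = 0
        d.iloc[idx, d.columns.get_loc("pseudo_tp")] = 1
        rep = {"replicate": i, "n_pseudo": n_tp}
        for mode in modes:
            rep[mode] = EndogenousTreatmentProbit(spec, mode=mode).fit(d).result_
        replicates.append(rep)
    return PlaceboResult(replicates=replicates, n_pseudo=n_tp)
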