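"""Batch-turn-down detection and targeted-placement labeling.

A transplanted kidney is a *targeted placement* (TP) when, within the match
run and at the recipient's own program: (1) at least five candidates
received a submitted initial response; (2) at least ``threshold`` (default
4) higher-ranked candidates share one initial decision code ("N" or "Z")
*and* one initial response timestamp — the batch turn down (BTD); and
(3) that shared timestamp is at or after the program's initial response for
the recipient.  Three code patterns distinguish the rules:

* Rule 1 — the batch is "N"; the recipient's initial response is "Y" or "Z".
* Rule 2 — the batch is "Z"; the recipient's initial response is "Y", or
  "Z" with identical initial and final date-time.
* Rule 3 — batch and recipient are both "Z", and the batch members' final
  response times fall after the recipient's final response time or on/after
  the transplant day.

Rules are evaluated in a configurable precedence (default 1, 2, 3; first
match wins), so every TP carries exactly one rule id.  "Same time" means
equality at minute resolution.  Batch membership is not broken by
intervening candidates without a submitted response.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import pandas as pd

RULES = (1, 2, 3)
MIN_ELIGIBLE_GROUP = 5


@dataclasses.dataclass(frozen=True)
class BTDEvent:
    """One batch turn down attached to a labeled targeted placement."""

    match_run_id: str
    donor_id: str
    txp_id: str
    recipient_ptr_id: str
    skipped_ptr_ids: tuple[str, ...]
    batch_code: str
    batch_time: pd.Timestamp

    @property
    def batch_size(self) -> int:
        return len(self.skipped_ptr_ids)

    def __post_init__(self):
        if self.batch_code not in ("N", "Z"):
            raise ValueError(f"batch code must be N or Z, got {self.batch_code}")


@dataclasses.dataclass(frozen=True)
class TPLabelResult:
    """Label for one transplant: TP/NTP, matching rule and its batch."""

    is_tp: bool
    rule_id: int                      # 0 when NTP
    event: Optional[BTDEvent]
    threshold: int

    def __post_init__(self):
        if self.is_tp != (self.rule_id in RULES):
            raise ValueError("label=TP iff a rule matched")


def detect_candidate_groups(
    offers: pd.DataFrame, min_group: int = MIN_ELIGIBLE_GROUP
) -> dict[tuple[str, str], tuple[pd.DataFrame, bool]]:
    """Per (match run, program): responding candidates in priority order.

    Only offers with a submitted initial response count.  Groups with fewer
    than ``min_group`` responding candidates are marked ineligible
    (criterion (1)).  Returns ``{(match_run_id, txp_id): (frame, eligible)}``.
    """
    responded = offers.loc[offers["initial_response"].notna()]
    out: dict[tuple[str, str], tuple[pd.DataFrame, bool]] = {}
    for key, g in responded.groupby(["match_run_id", "txp_id"], sort=False):
        g = g.sort_values("sequence_number").reset_index(drop=True)
        out[key] = (g, len(g) >= min_group)
    return out


def _enumerate_batches(higher: pd.DataFrame):
    """Maximal same-code same-minute pools among the higher-ranked responding
    candidates, largest first then earliest.  Per-rule thresholding happens
    at match time (a Rule-3 sub-batch may be smaller than its pool)."""
    mask = higher["initial_response"].isin(["N", "Z"]) & higher["initial_response_time"].notna()
    pool = higher.loc[mask]
    batches = []
    for (code, time), g in pool.groupby(["initial_response", "initial_response_time"]):
        batches.append((code, time, g))
    batches.sort(key=lambda b: (-len(b[2]), b[1], b[0]))
    return batches


def _final_time_subbatch(batch: pd.DataFrame, rec_final: pd.Timestamp,
                         transplant_date: Optional[pd.Timestamp]) -> pd.DataFrame:
    """Members whose final response time is after the recipient's final
    response time, or on/after the transplant day."""
    ft = batch["final_response_time"]
    after_rec = ft.notna() & pd.notna(rec_final) & (ft > rec_final)
    if transplant_date is not None and pd.notna(transplant_date):
        on_or_after_tx = ft.notna() & (
            ft.dt.normalize() >= pd.Timestamp(transplant_date).normalize())
    else:
        on_or_after_tx = pd.Series(False, index=ft.index)
    return batch.loc[after_rec | on_or_after_tx]


def label_transplant(
    group: pd.DataFrame,
    accepted_ptr: str,
    threshold: int = 4,
    *,
    transplant_date: Optional[pd.Timestamp] = None,
    rule_precedence: tuple[int, ...] = RULES,
    strict_final_time: bool = False,
    min_group: int = MIN_ELIGIBLE_GROUP,
) -> TPLabelResult:
    """Label one transplanted offer against its program's response group.

    ``group`` holds the responding candidates of one (match run, program),
    any order; ``accepted_ptr`` must be among them.  ``strict_final_time``
    extends the Rule-3 final-time condition to Rule-2 "Z" batches.
    """
    if accepted_ptr not in set(group["ptr_id"]):
        raise ValueError(f"accepted ptr {accepted_ptr!r} not in group")
    ntp = TPLabelResult(False, 0, None, threshold)
    g = group.loc[group["initial_response"].notna()].sort_values("sequence_number")
    if len(g) < min_group:
        return ntp
    rec = g.loc[g["ptr_id"] == accepted_ptr].iloc[0]
    rec_time = rec["initial_response_time"]
    if pd.isna(rec_time):
        return ntp
    higher = g.loc[g["sequence_number"] < rec["sequence_number"]]
    batches = _enumerate_batches(higher)
    if not batches:
        return ntp

    rec_code = rec["initial_response"]
    rec_final = rec["final_response_time"]
    for rule in rule_precedence:
        for code, time, pool in batches:
            if time < rec_time:      # criterion (3)
                continue
            batch = pool
            if rule == 1:
                ok = code == "N" and rec_code in ("Y", "Z")
            elif rule == 2:
                ok = code == "Z" and (
                    rec_code == "Y"
                    or (rec_code == "Z" and pd.notna(rec_final) and rec_final == rec_time)
                )
                if ok and strict_final_time:
                    batch = _final_time_subbatch(pool, rec_final, transplant_date)
            elif rule == 3:
                ok = code == "Z" and rec_code == "Z"
                if ok:
                    batch = _final_time_subbatch(pool, rec_final, transplant_date)
            else:
                raise ValueError(f"unknown rule {rule}")
            if ok and len(batch) >= threshold:
                event = BTDEvent(
                    match_run_id=str(rec["match_run_id"]) if "match_run_id" in rec else "",
                    donor_id=str(rec["donor_id"]) if "donor_id" in rec else "",
                    txp_id=str(rec["txp_id"]) if "txp_id" in rec else "",
                    recipient_ptr_id=accepted_ptr,
                    skipped_ptr_ids=tuple(batch["ptr_id"]),
                    batch_code=code,
                    batch_time=time,
                )
                return TPLabelResult(True, rule, event, threshold)
    return ntp


def label_cohort(
    cohort,
    threshold: int = 4,
    *,
    rule_precedence: tuple[int, ...] = RULES,
    strict_final_time: bool = False,
) -> tuple[pd.DataFrame, list[BTDEvent]]:
    """Label every transplant in a prepped cohort; collect BTD events.

    Only batches attached to a labeled TP define BTD membership — turn downs
    never followed by a targeted transplant are not recorded, mirroring the
    construction (and the stated limitation) of the source methodology.

    Returns ``(labels, events)``: one label row per transplant with columns
    ``donor_id, ptr_id, match_run_id, txp_id, is_tp, rule_id, batch_size,
    batch_time, transplant_date``, and the BTDEvent list.
    """
    offers = cohort.offers
    groups = {key: g for key, g in
              offers.loc[offers["initial_response"].notna()]
              .groupby(["match_run_id", "txp_id"], sort=False)}
    # accepting offer per transplant: the offer row of the transplant key
    acc = offers.merge(
        cohort.transplants[["donor_id", "ptr_id", "transplant_date"]],
        on=["donor_id", "ptr_id"], how="inner")
    acc = acc.loc[acc["final_response"].isin(["Y", "Z"]) | (acc["initial_response"] == "Y")]
    acc_by_key = {(r.donor_id, r.ptr_id): r for r in acc.itertuples(index=False)}

    rows = []
    events: list[BTDEvent] = []
    for tx in cohort.transplants.itertuples(index=False):
        key = (tx.donor_id, tx.ptr_id)
        offer = acc_by_key.get(key)
        if offer is None:
            rows.append({"donor_id": tx.donor_id, "ptr_id": tx.ptr_id,
                         "match_run_id": None, "txp_id": tx.txp_id, "is_tp": False,
                         "rule_id": 0, "batch_size": 0, "batch_time": pd.NaT,
                         "accept_time": pd.NaT, "transplant_date": tx.transplant_date})
            continue
        group = groups.get((offer.match_run_id, offer.txp_id))
        if group is None:
            result = TPLabelResult(False, 0, None, threshold)
        else:
            result = label_transplant(
                group, tx.ptr_id, threshold,
                transplant_date=tx.transplant_date,
                rule_precedence=rule_precedence,
                strict_final_time=strict_final_time,
            )
        if result.event is not None:
            events.append(result.event)
        rows.append({
            "donor_id": tx.donor_id, "ptr_id": tx.ptr_id,
            "match_run_id": offer.match_run_id, "txp_id": offer.txp_id,
            "is_tp": result.is_tp, "rule_id": result.rule_id,
            "batch_size": result.event.batch_size if result.event else 0,
            "batch_time": result.event.batch_time if result.event else pd.NaT,
            "accept_time": offer.initial_response_time,
            "transplant_date": tx.transplant_date,
        })
    labels = pd.DataFrame(rows, columns=["donor_id", "ptr_id", "match_run_id", "txp_id",
                                         "is_tp", "rule_id", "batch_size", "batch_time",
                                         "accept_time", "transplant_date"])
    return labels, events


def classify_entities(labels: pd.DataFrame, cohort, events: Iterable[BTDEvent]):
    """Classify donors (TP/NTP), recipients (TP/NTP and BTD/non-BTD) and
    candidates (BTD/non-BTD).

    A donor is TP if at least one of its kidneys was transplanted as TP.  A
    recipient is a BTD recipient if they were a batch member strictly before
    their own transplant date; a candidate is a BTD candidate if they were a
    batch member at any point.
    """
    donors = cohort.donors[["donor_id"]].copy()
    donors["tp_donor"] = donors["donor_id"].isin(labels.loc[labels["is_tp"], "donor_id"])
    donors["transplanted"] = donors["donor_id"].isin(labels["donor_id"])

    ev_rows = [
        {"ptr_id": p, "batch_time": e.batch_time}
        for e in events for p in e.skipped_ptr_ids
    ]
    ev = pd.DataFrame(ev_rows, columns=["ptr_id", "batch_time"])

    recipients = labels[["ptr_id", "is_tp", "transplant_date"]].rename(
        columns={"is_tp": "tp_recipient"}).copy()
    if len(ev):
        first_skip = ev.groupby("ptr_id")["batch_time"].min()
        skipped_at = recipients["ptr_id"].map(first_skip)
        recipients["btd_recipient"] = (
            skipped_at.notna() & (skipped_at < recipients["transplant_date"])
        )
    else:
        recipients["btd_recipient"] = False

    candidates = cohort.candidates[["ptr_id"]].copy()
    candidates["btd_candidate"] = candidates["ptr_id"].isin(set(ev["ptr_id"]))
    candidates["recipient"] = candidates["ptr_id"].isin(labels["ptr_id"])
    return {"donors": donors, "recipients": recipients, "candidates": candidates}


class TPLabeler:
    """Transform-style wrapper around :func:`label_cohort`.

    Parameters mirror the function; after :meth:`fit`, ``labels_`` and
    ``events_`` hold the per-transplant labels and BTD events and
    ``rule_counts_`` the TP tally per rule.
    """

    def __init__(self, threshold: int = 4, rule_precedence: tuple[int, ...] = RULES,
                 strict_final_time: bool = False):
        self.threshold = threshold
        self.rule_precedence = rule_precedence
        self.strict_final_time = strict_final_time

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "rule_precedence": self.rule_precedence,
                "strict_final_time": self.strict_final_time}

    def set_params(self, **params) -> "TPLabeler":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, cohort, y=None) -> "TPLabeler":
        self.labels_, self.events_ = label_cohort(
            cohort, self.threshold, rule_precedence=self.rule_precedence,
            strict_final_time=self.strict_final_time)
        counts = self.labels_.loc[self.labels_["is_tp"], "rule_id"].value_counts()
        self.rule_counts_ = {r: int(counts.get(r, 0)) for r in RULES}
        self.n_tp_ = int(self.labels_["is_tp"].sum())
        return self

    def transform(self, cohort) -> pd.DataFrame:
        if not hasattr(self, "labels_"):
            raise AttributeError("TPLabeler is not fitted; call fit first")
        return self.labels_

    def fit_transform(self, cohort, y=None) -> pd.DataFrame:
        return self.fit(cohort).transform(cohort)
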