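"""Study-cohort preparation: response normalization and the filter chain.

The chain removes offer records in which an out-of-sequence placement could
have been clinically justified or the record is atypical, so that the
labeling rules only see candidates a program genuinely chose between:
pediatric donors or recipients, dual-kidney and multi-organ transplants,
match runs resolved through OPO bypass actions, open offers, and
inconsistent accept/decline records.  Each step logs ``(name, n_in,
n_out)`` offer counts into the cohort provenance log; the chain is
idempotent and never adds records.

A separate switchable filter removes offers declined for refusal code 801
("patient ill, unavailable, refused, or temporarily unsuitable") or with a
free-text refusal reason, since such declines are candidate-specific rather
than batch-like.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import Cohort

PEDIATRIC_AGE_CUTOFF = 18.0

#: canonical step order of the preparation chain
PREP_STEPS = (
    "date_window",
    "pediatric",
    "dual_kidney",
    "multi_organ",
    "bypass",
    "open_offer",
    "atypical",
)


@dataclasses.dataclass
class PrepConfig:
    enabled_steps: tuple[str, ...] = PREP_STEPS
    date_start: str = "2015-01-01"
    date_end: str = "2018-12-31"
    pediatric_cutoff: float = PEDIATRIC_AGE_CUTOFF
    rc1: bool = False  # also apply the refusal-801 / free-text filter

    def __post_init__(self) -> None:
        unknown = set(self.enabled_steps) - set(PREP_STEPS)
        if unknown:
            raise ValueError(f"unknown prep steps: {sorted(unknown)}")
        # order is fixed regardless of the order given
        self.enabled_steps = tuple(s for s in PREP_STEPS if s in self.enabled_steps)


def normalize_responses(cohort: Cohort) -> Cohort:
    """Reinterpret stale terminal provisional-yes codes on transplanted offers.

    A "Z" final response on the offer whose candidate actually received that
    donor's kidney means the code was never updated after acceptance; it is
    rewritten to "Y".  All other codes are untouched.
    """
    out = cohort.copy()
    tx_keys = set(zip(cohort.transplants["donor_id"], cohort.transplants["ptr_id"]))
    off = out.offers
    is_tx_offer = pd.Series(
        [k in tx_keys for k in zip(off["donor_id"], off["ptr_id"])], index=off.index
    )
    stale = is_tx_offer & (off["final_response"] == "Z")
    off.loc[stale, "final_response"] = "Y"
    out.log_step("normalize_stale_z", len(off), len(off))
    return out


def _drop_runs(cohort: Cohort, run_ids: set) -> None:
    """Drop all offers of the given match runs and their transplants."""
    off = cohort.offers
    doomed = off["match_run_id"].isin(run_ids)
    doomed_tx = set(zip(off.loc[doomed, "donor_id"], off.loc[doomed, "ptr_id"]))
    cohort.offers = off.loc[~doomed].reset_index(drop=True)
    tx = cohort.transplants
    keep = [k not in doomed_tx or k in set(
        zip(cohort.offers["donor_id"], cohort.offers["ptr_id"]))
        for k in zip(tx["donor_id"], tx["ptr_id"])]
    cohort.transplants = tx.loc[keep].reset_index(drop=True)


def apply_prep_pipeline(cohort: Cohort, config: PrepConfig | None = None) -> Cohort:
    """Run the (enabled subset of the) seven-step filter chain, logging counts.

    Steps, in fixed order: restrict offers to the study date window; drop
    pediatric donors/recipients; drop dual-kidney transplants; drop
    multi-organ transplants; drop match runs resolved by bypass ("B"
    responses); drop open-offer placements; drop atypical records
    (timestamp-order violations, acceptances with no transplant).
    """
    config = config or PrepConfig()
    out = cohort.copy()
    start, end = pd.Timestamp(config.date_start), pd.Timestamp(config.date_end)

    for step in PREP_STEPS:
        n_in = len(out.offers)
        if step not in config.enabled_steps:
            continue
        off = out.offers
        if step == "date_window":
            t = off["initial_response_time"]
            keep = t.isna() | ((t >= start) & (t < end + pd.Timedelta(days=1)))
            out.offers = off.loc[keep].reset_index(drop=True)
            _sync_transplants(out)
        elif step == "pediatric":
            ped_donors = set(out.donors.loc[out.donors["age"] < config.pediatric_cutoff,
                                            "donor_id"])
            ped_cands = set(out.candidates.loc[
                out.candidates["age_at_listing"] < config.pediatric_cutoff, "ptr_id"])
            runs = set(off.loc[off["donor_id"].isin(ped_donors), "match_run_id"])
            keep = ~off["match_run_id"].isin(runs) & ~off["ptr_id"].isin(ped_cands)
            out.offers = off.loc[keep].reset_index(drop=True)
            _sync_transplants(out)
        elif step == "dual_kidney":
            flagged = out.transplants.loc[out.transplants["dual_kidney"], ["donor_id", "ptr_id"]]
            _drop_transplant_runs(out, flagged)
        elif step == "multi_organ":
            flagged = out.transplants.loc[out.transplants["multi_organ"], ["donor_id", "ptr_id"]]
            _drop_transplant_runs(out, flagged)
        elif step == "bypass":
            has_b = (off["initial_response"] == "B") | (off["final_response"] == "B")
            runs = set(off.loc[has_b, "match_run_id"])
            _drop_runs(out, runs)
        elif step == "open_offer":
            runs = set(off.loc[off["open_offer"], "match_run_id"])
            _drop_runs(out, runs)
        elif step == "atypical":
            both = off["initial_response_time"].notna() & off["final_response_time"].notna()
            bad_time = both & (off["final_response_time"] < off["initial_response_time"])
            tx_keys = set(zip(out.transplants["donor_id"], out.transplants["ptr_id"]))
            accepted = off["final_response"] == "Y"
            no_tx = accepted & np.array(
                [k not in tx_keys for k in zip(off["donor_id"], off["ptr_id"])],
                dtype=bool)
            out.offers = off.loc[~(bad_time | no_tx)].reset_index(drop=True)
            _sync_transplants(out)
        out.log_step(f"prep_{step}", n_in, len(out.offers))

    if config.rc1:
        out = filter_refusal_801(out)
    return out


def _sync_transplants(cohort: Cohort) -> None:
    """Keep only transplants whose accepting offer survives in the offer table."""
    off_keys = set(zip(cohort.offers["donor_id"], cohort.offers["ptr_id"]))
    tx = cohort.transplants
    keep = [k in off_keys for k in zip(tx["donor_id"], tx["ptr_id"])]
    cohort.transplants = tx.loc[keep].reset_index(drop=True)


def _drop_transplant_runs(cohort: Cohort, flagged: pd.DataFrame) -> None:
    if len(flagged) == 0:
        return
    off = cohort.offers
    keys = set(zip(flagged["donor_id"], flagged["ptr_id"]))
    runs = set(off.loc[[k in keys for k in zip(off["donor_id"], off["ptr_id"])],
                       "match_run_id"])
    _drop_runs(cohort, runs)
    # the transplant record itself goes regardless of whether a run matched
    tx = cohort.transplants
    keep = [k not in keys for k in zip(tx["donor_id"], tx["ptr_id"])]
    cohort.transplants = tx.loc[keep].reset_index(drop=True)


def filter_refusal_801(cohort: Cohort) -> Cohort:
    """Remove offers declined for code 801 or a free-text refusal reason.

    A refusal reason is treated as free text when it is present and not a
    purely numeric code.  The remaining records re-enter labeling unchanged.
    """
    out = cohort.copy()
    off = out.offers
    n_in = len(off)
    rc = off["refusal_code"]
    declined = off["final_response"].isin(["N", "Z"]) | off["initial_response"].isin(["N", "Z"])
    is_801 = rc == "801"
    free_text = rc.notna() & ~rc.fillna("").str.fullmatch(r"\d+")
    out.offers = off.loc[~(declined & (is_801 | free_text))].reset_index(drop=True)
    out.log_step("filter_refusal_801", n_in, len(out.offers))
    return out
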