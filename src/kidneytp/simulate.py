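"""Synthetic match-run generator with known ground truth.

Emulates the structure of national registry (STAR-like) and match-run
(PTR-like) extracts: per-donor priority-ordered candidate lists, per-program
response batches with shared timestamps, a targeted-placement (TP)
propensity driven by recipient age, donor KDPI and recipient EPTS through a
latent probit threshold, and 1-year patient-and-graft survival generated
from a second latent probit whose error is correlated with the treatment
error (correlation ``rho``) — the endogeneity the estimation modules are
built to undo.

The generative story per kidney:

1. a match run is drawn — candidates sampled mostly from the donor's DSA so
   that one *focal* program holds a contiguous-enough block of candidates;
2. the focal program's target candidate ``j`` (the one with ``b`` same-
   program candidates ranked above it, ``b`` drawn from the batch-size
   distribution) receives the kidney either way;
3. latent errors ``(xi, eps)`` are drawn bivariate normal with correlation
   ``rho``; the placement is targeted iff
   ``alpha0 + a_age*age_j + a_kdpi*kdpi_i + a_epts*epts_j + xi > 0``;
4. if targeted, the ``b`` higher-ranked same-program candidates receive a
   batch of identical-code ("N" or "Z", per the configured rule mixture),
   identical-timestamp initial responses at or after the recipient's initial
   response; otherwise every higher-ranked candidate declines sequentially
   at distinct minutes;
5. survival is ``1[beta0 + beta1*TP + b_kdpi*kdpi + b_age*age + b_epts*epts
   + eps > 0]``.

Bypass-resolved runs, pediatric donors/candidates, open offers, dual/multi-
organ transplants and refusal-code-801 declines are injected at configured
rates so the preparation filter chain has something to remove.  With the
default (zero) timestamp jitter the labeling rules recover the true TP flags
exactly; jitter splits batch timestamps and degrades recovery.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, empty_cohort

_REFUSAL_CODES = ["830", "831", "837", "841"]


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions.

    TP-propensity coefficients default to the recipient-age / KDPI / EPTS
    effects of the treatment-assignment probit and an intercept putting the
    marginal TP share near 7%; the outcome intercept puts marginal survival
    near 95%.  ``beta1`` (treatment effect on the latent survival index) and
    ``rho`` (error correlation) default to the null.
    """

    n_donors: int = 600
    n_candidates: int = 5000
    n_programs: int = 20
    n_dsas: int = 5
    date_start: str = "2015-01-01"
    date_end: str = "2018-12-31"
    # share of donors with both kidneys placed
    p_two_kidneys: float = 0.684
    run_length_mean: float = 28.0
    local_share: float = 0.7
    # Eq-style TP propensity: alpha0 + a_age*age + a_kdpi*kdpi + a_epts*epts + xi > 0
    alpha0: float = -2.7
    alpha_age: float = 0.026
    alpha_kdpi: float = 0.395
    alpha_epts: float = -0.613
    # latent survival index
    beta0: float = 2.9
    beta1: float = 0.0
    beta_kdpi: float = -1.0
    beta_age: float = -0.01
    beta_epts: float = -0.5
    rho: float = 0.0
    # labeling-rule mixture for generated TP events (batch "N"; batch "Z" with
    # immediate recipient acceptance; batch "Z" with provisional recipient)
    rule_mixture: tuple[float, float, float] = (0.145, 0.078, 0.777)
    batch_sizes: tuple[int, ...] = (4, 5, 6, 7, 8)
    batch_size_probs: tuple[float, ...] = (0.40, 0.25, 0.15, 0.10, 0.10)
    # timestamp jitter (minutes, sd) applied to batch members; 0 = noiseless
    jitter_sd_min: float = 0.0
    # injection rates for the preparation filter chain
    bypass_rate: float = 0.03
    pediatric_donor_rate: float = 0.02
    pediatric_candidate_rate: float = 0.02
    open_offer_rate: float = 0.01
    dual_kidney_rate: float = 0.01
    multi_organ_rate: float = 0.01
    refusal_801_rate: float = 0.05
    free_text_rate: float = 0.02
    notify_time_rate: float = 0.328
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        for field in ("n_donors", "n_candidates", "n_programs", "n_dsas"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be nonnegative")
        if abs(sum(self.rule_mixture) - 1.0) > 1e-9:
            raise ValueError("rule_mixture must sum to 1")


@dataclasses.dataclass
class GroundTruth:
    """True generator state, for recovery testing.

    ``transplants`` has one row per transplant with the true TP flag, the
    generating rule id (0 = not targeted) and the latent errors; ``btd``
    has one row per true batch-member offer.
    """

    transplants: pd.DataFrame  # donor_id, ptr_id, match_run_id, true_tp, rule_id, xi, eps
    btd: pd.DataFrame          # match_run_id, ptr_id
    config: SimConfig


def _rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed))


def simulate_registry(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Cohort:
    """Draw donors, candidates, programs and DSAs into a Cohort skeleton.

    Donor KDPI is positively associated with donor age; candidate EPTS with
    candidate age.  Each candidate lists at one program; each program sits in
    one DSA.  Offer and transplant tables are left empty.
    """
    rng = rng or _rng(config)
    cohort = empty_cohort()
    start = pd.Timestamp(config.date_start)
    end = pd.Timestamp(config.date_end)

    n_d = config.n_donors
    if n_d:
        age = np.clip(rng.normal(42.0, 14.0, n_d), 18.0, 80.0)
        ped = rng.random(n_d) < config.pediatric_donor_rate
        age[ped] = rng.uniform(1.0, 17.0, int(ped.sum()))
        kdpi = np.clip(0.45 + 0.012 * (age - 42.0) + rng.normal(0.0, 0.22, n_d), 0.01, 0.99)
        cohort.donors = pd.DataFrame({
            "donor_id": [f"D{i:06d}" for i in range(n_d)],
            "kdpi": kdpi,
            "age": np.round(age, 1),
            "race": rng.choice(["White", "Black", "Hispanic", "Other"], n_d,
                               p=[0.62, 0.16, 0.15, 0.07]),
            "diabetes": pd.array((rng.random(n_d) < 0.08 + 0.1 * kdpi).astype(int), dtype="Int64"),
            "creatinine": np.round(np.exp(rng.normal(0.0, 0.45, n_d)), 2),
            "cause_of_death": rng.choice(["Anoxia", "Stroke", "HeadTrauma", "Other"], n_d,
                                         p=[0.4, 0.25, 0.28, 0.07]),
        })

    programs = [f"T{i:03d}" for i in range(config.n_programs)]
    dsa_of_program = {p: f"DSA{i % max(config.n_dsas, 1):02d}" for i, p in enumerate(programs)}
    # Zipf-ish program volumes: high-volume programs list more candidates
    w = 1.0 / np.arange(1, config.n_programs + 1) ** 0.6
    w /= w.sum()

    n_c = config.n_candidates
    if n_c:
        cage = np.clip(rng.normal(52.0, 13.0, n_c), 18.0, 80.0)
        pedc = rng.random(n_c) < config.pediatric_candidate_rate
        cage[pedc] = rng.uniform(2.0, 17.0, int(pedc.sum()))
        epts = np.clip(0.5 + 0.013 * (cage - 52.0) + rng.normal(0.0, 0.16, n_c), 0.01, 0.99)
        txp = rng.choice(programs, n_c, p=w)
        listing = start - pd.Timedelta(days=4 * 365) + pd.to_timedelta(
            rng.uniform(0.0, ((end - pd.Timedelta(days=30)) - (start - pd.Timedelta(days=4 * 365))).days,
                        n_c), unit="D")
        cohort.candidates = pd.DataFrame({
            "ptr_id": [f"P{i:07d}" for i in range(n_c)],
            "txp_id": txp,
            "dsa_id": [dsa_of_program[t] for t in txp],
            "epts": epts,
            "age_at_listing": np.round(cage, 1),
            "sex": rng.choice(["M", "F"], n_c, p=[0.61, 0.39]),
            "race": rng.choice(["White", "Black", "Hispanic", "Other"], n_c,
                               p=[0.38, 0.31, 0.2, 0.11]),
            "listing_date": pd.Series(listing).dt.normalize(),
        })
    return cohort


def _minute(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor("min")


def simulate_match_runs(
    registry: Cohort, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Cohort, GroundTruth]:
    """Generate offers, responses with timestamps, transplants and truth.

    Returns a full Cohort (transplant ``survival_1yr`` left missing — filled
    by :func:`simulate_outcomes`) and the :class:`GroundTruth`.
    """
    rng = rng or _rng(config)
    if len(registry.donors) == 0 or len(registry.candidates) == 0:
        gt = GroundTruth(pd.DataFrame(columns=["donor_id", "ptr_id", "match_run_id",
                                               "true_tp", "rule_id", "xi", "eps"]),
                         pd.DataFrame(columns=["match_run_id", "ptr_id"]), config)
        out = registry.copy()
        return out, gt

    start = pd.Timestamp(config.date_start)
    end = pd.Timestamp(config.date_end)
    # flat arrays sorted by listing date: the waitlist
    cand = registry.candidates.sort_values("listing_date").reset_index(drop=True)
    c_ids = cand["ptr_id"].to_numpy(object)
    c_listing = cand["listing_date"].to_numpy()
    c_epts = cand["epts"].to_numpy(float)
    c_age = cand["age_at_listing"].to_numpy(float)
    c_txp = cand["txp_id"].to_numpy(object)
    c_dsa = cand["dsa_id"].to_numpy(object)
    taken = np.zeros(len(cand), dtype=bool)
    programs = sorted(set(c_txp))
    dsa_of_program = {t: d for t, d in zip(c_txp, c_dsa)}

    offer_rows: list[dict] = []
    tx_rows: list[dict] = []
    truth_rows: list[dict] = []
    btd_rows: list[dict] = []

    # one kidney event per placement, in calendar order so that a candidate
    # leaves the waitlist once transplanted
    kidney_donors: list[tuple] = []
    for donor in registry.donors[["donor_id", "kdpi"]].itertuples(index=False):
        n_kid = 2 if rng.random() < config.p_two_kidneys else 1
        for _ in range(n_kid):
            run_date = _minute(start + pd.Timedelta(
                days=float(rng.uniform(0, (end - start).days)),
                hours=float(rng.uniform(0, 24))))
            kidney_donors.append((run_date, donor.donor_id, donor.kdpi))
    kidney_donors.sort(key=lambda t: t[0])

    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    lat = rng.multivariate_normal([0.0, 0.0], cov, size=len(kidney_donors))

    for run_no, (run_date, donor_id, kdpi) in enumerate(kidney_donors, start=1):
        match_run_id = f"MR{run_no:06d}"
        xi, eps = lat[run_no - 1]

        b = int(rng.choice(config.batch_sizes, p=config.batch_size_probs))
        focal = programs[int(rng.choice(len(programs)))]
        dsa = dsa_of_program[focal]

        # candidates listed before the run date and not yet transplanted
        nav = int(np.searchsorted(c_listing, np.datetime64(run_date)))
        open_mask = ~taken[:nav]
        focal_idx = np.flatnonzero(open_mask & (c_txp[:nav] == focal))
        n_focal = min(b + 1 + int(rng.poisson(1.5)), len(focal_idx))
        focal_sel = (rng.choice(focal_idx, size=n_focal, replace=False)
                     if n_focal else np.empty(0, dtype=int))
        run_len = max(int(rng.poisson(config.run_length_mean)), n_focal + 5)
        n_other = run_len - n_focal
        other_idx = np.flatnonzero(open_mask & (c_txp[:nav] != focal))
        if len(other_idx) > n_other:
            # weight toward the donor's DSA
            wts = np.where(c_dsa[other_idx] == dsa, config.local_share,
                           1.0 - config.local_share)
            other_sel = rng.choice(other_idx, size=n_other, replace=False,
                                   p=wts / wts.sum())
        else:
            other_sel = other_idx
        sel = np.concatenate([focal_sel, other_sel])
        if len(sel) == 0:
            continue
        sel = sel[rng.permutation(len(sel))]
        r_ids, r_txp = c_ids[sel], c_txp[sel]
        r_epts, r_age = c_epts[sel], c_age[sel]

        focal_pos = np.flatnonzero(r_txp == focal)
        feasible = len(focal_pos) >= b + 1
        if feasible:
            rec_pos = int(focal_pos[b])     # b same-program candidates ranked above
        else:
            rec_pos = int(focal_pos[-1]) if len(focal_pos) else 0

        rec_global = int(sel[rec_pos])
        rec_ptr = c_ids[rec_global]
        rec_listing = pd.Timestamp(c_listing[rec_global])
        rec_epts = float(c_epts[rec_global])
        rec_age = float(c_age[rec_global]) + (run_date - rec_listing).days / 365.25
        tp_index = (config.alpha0 + config.alpha_age * rec_age
                    + config.alpha_kdpi * kdpi + config.alpha_epts * rec_epts)
        is_tp = bool(feasible and (tp_index + xi > 0))
        rule = int(rng.choice([1, 2, 3], p=config.rule_mixture)) if is_tp else 0

        bypass_run = rng.random() < config.bypass_rate
        open_run = (not bypass_run) and (rng.random() < config.open_offer_rate)

        t0 = run_date
        t_rec = _minute(t0 + pd.Timedelta(minutes=float(rng.uniform(30, 120))))
        t_batch = _minute(t_rec + pd.Timedelta(minutes=float(rng.integers(0, 61))))
        transplant_date = (run_date + pd.Timedelta(days=float(rng.uniform(1, 3)))).normalize()

        batch_pos = set(focal_pos[:b]) if is_tp else set()
        seq_time = t0
        for pos in range(len(sel)):
            o = {
                "match_run_id": match_run_id,
                "donor_id": donor_id,
                "ptr_id": r_ids[pos],
                "txp_id": r_txp[pos],
                "sequence_number": pos + 1,
                "initial_response": None,
                "initial_response_time": pd.NaT,
                "final_response": None,
                "final_response_time": pd.NaT,
                "notify_time": t0 if rng.random() < config.notify_time_rate else pd.NaT,
                "refusal_code": None,
                "open_offer": False,
            }
            if pos < rec_pos and pos not in batch_pos:
                # sequential decline at a distinct minute
                seq_time = _minute(seq_time + pd.Timedelta(minutes=float(rng.integers(2, 9))))
                decline_time = min(seq_time, t_rec - pd.Timedelta(minutes=1))
                o.update(initial_response="N", initial_response_time=decline_time,
                         final_response="N", final_response_time=decline_time,
                         refusal_code=_refusal(rng, config))
                if bypass_run and rng.random() < 0.5:
                    o["initial_response"] = "B"
                    o["final_response"] = "B"
                    o["refusal_code"] = None
            elif pos in batch_pos:
                bt = t_batch
                if config.jitter_sd_min > 0:
                    bt = _minute(bt + pd.Timedelta(
                        minutes=float(rng.normal(0.0, config.jitter_sd_min))))
                code = "N" if rule == 1 else "Z"
                if rule == 3:
                    ft = transplant_date + pd.Timedelta(
                        days=float(rng.integers(0, 3)), hours=float(rng.uniform(8, 18)))
                    ft = _minute(ft)
                    fcode = "N"
                elif rule == 2:
                    ft = _minute(bt + pd.Timedelta(hours=float(rng.uniform(2, 24))))
                    fcode = "N"
                else:
                    ft, fcode = bt, "N"
                o.update(initial_response=code, initial_response_time=bt,
                         final_response=fcode, final_response_time=max(ft, bt),
                         refusal_code=_refusal(rng, config))
                btd_rows.append({"match_run_id": match_run_id, "ptr_id": r_ids[pos]})
            elif pos == rec_pos:
                if is_tp:
                    if rule == 1:
                        o.update(initial_response="Y", initial_response_time=t_rec,
                                 final_response="Y", final_response_time=t_rec)
                    elif rule == 2:
                        if rng.random() < 0.5:
                            o.update(initial_response="Y", initial_response_time=t_rec,
                                     final_response="Y", final_response_time=t_rec)
                        else:
                            # stale provisional-yes: accepted and transplanted,
                            # code never updated; initial == final datetime
                            o.update(initial_response="Z", initial_response_time=t_rec,
                                     final_response="Z", final_response_time=t_rec)
                    else:
                        frt = _minute(t_rec + pd.Timedelta(hours=float(rng.uniform(1, 12))))
                        o.update(initial_response="Z", initial_response_time=t_rec,
                                 final_response="Z", final_response_time=frt)
                else:
                    seq_time = _minute(seq_time + pd.Timedelta(minutes=float(rng.integers(2, 9))))
                    acc_time = max(seq_time, t_rec)
                    o.update(initial_response="Y", initial_response_time=acc_time,
                             final_response="Y", final_response_time=acc_time,
                             open_offer=open_run)
            # candidates ranked below the recipient: no response recorded
            offer_rows.append(o)

        tx_rows.append({
            "donor_id": donor_id,
            "ptr_id": rec_ptr,
            "txp_id": r_txp[rec_pos],
            "transplant_date": transplant_date,
            "cit_hours": round(max(float(rng.normal(16.3 + (3.7 if is_tp else 0.0), 5.0)), 2.0), 1),
            "time_to_transplant": round((transplant_date - rec_listing).days / 365.25, 3),
            "survival_1yr": None,
            "dual_kidney": bool(rng.random() < config.dual_kidney_rate),
            "multi_organ": bool(rng.random() < config.multi_organ_rate),
        })
        truth_rows.append({
            "donor_id": donor_id, "ptr_id": rec_ptr, "match_run_id": match_run_id,
            "true_tp": int(is_tp), "rule_id": rule, "xi": xi, "eps": eps,
            "rec_age": float(rec_age), "kdpi": float(kdpi), "epts": rec_epts,
        })
        taken[rec_global] = True

    out = registry.copy()
    out.offers = pd.DataFrame(offer_rows)
    for col in ("initial_response_time", "final_response_time", "notify_time"):
        out.offers[col] = pd.to_datetime(out.offers[col])
    out.offers["sequence_number"] = pd.array(out.offers["sequence_number"], dtype="Int64")
    out.transplants = pd.DataFrame(tx_rows)
    out.transplants["transplant_date"] = pd.to_datetime(out.transplants["transplant_date"])
    out.transplants["survival_1yr"] = pd.array([None] * len(out.transplants), dtype="Int64")
    gt = GroundTruth(pd.DataFrame(truth_rows),
                     pd.DataFrame(btd_rows, columns=["match_run_id", "ptr_id"]), config)
    return out, gt


def _refusal(rng: np.random.Generator, config: SimConfig):
    u = rng.random()
    if u < config.refusal_801_rate:
        return "801"
    if u < config.refusal_801_rate + config.free_text_rate:
        return "other reason given"
    return str(rng.choice(_REFUSAL_CODES))


def simulate_outcomes(cohort: Cohort, truth: GroundTruth, config: SimConfig) -> Cohort:
    """Fill ``survival_1yr`` from the latent outcome index and stored errors.

    ``Y* = beta0 + beta1*TP + beta_kdpi*KDPI + beta_age*age + beta_epts*EPTS
    + eps``; survival = ``1[Y* > 0]``, with ``eps`` the member of the
    bivariate-normal pair realized at match-run generation (so treatment and
    outcome errors carry correlation ``rho``).
    """
    if not -1.0 < config.rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    out = cohort.copy()
    t = truth.transplants
    if len(t) == 0:
        return out
    ystar = (config.beta0 + config.beta1 * t["true_tp"]
             + config.beta_kdpi * t["kdpi"] + config.beta_age * t["rec_age"]
             + config.beta_epts * t["epts"] + t["eps"])
    surv = (ystar > 0).astype(int)
    surv_map = dict(zip(zip(t["donor_id"], t["ptr_id"]), surv))
    out.transplants["survival_1yr"] = pd.array(
        [surv_map.get((d, p)) for d, p in zip(out.transplants["donor_id"],
                                              out.transplants["ptr_id"])],
        dtype="Int64")
    return out


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Registry + match runs + outcomes in one deterministic call."""
    rng = _rng(config)
    registry = simulate_registry(config, rng)
    cohort, truth = simulate_match_runs(registry, config, rng)
    cohort = simulate_outcomes(cohort, truth, config)
    return cohort, truth


def simulate_transplant_table(
    n: int,
    *,
    beta1: float = 0.0,
    rho: float = 0.0,
    config: Optional[SimConfig] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Transplant-level draw from the latent two-equation process.

    Skips the match-run mechanics and draws ``(age, kdpi, epts)`` covariates,
    the treatment from the propensity threshold and survival from the outcome
    index directly — the workhorse for estimator-recovery studies at large n.
    Returns the table and the dict of generating parameters.
    """
    cfg = config or SimConfig()
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    age = np.clip(rng.normal(53.0, 12.0, n), 18.0, 80.0)
    kdpi = np.clip(0.45 + rng.normal(0.0, 0.24, n), 0.01, 0.99)
    epts = np.clip(0.5 + 0.012 * (age - 53.0) + rng.normal(0.0, 0.16, n), 0.01, 0.99)
    lat = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    xi, eps = lat[:, 0], lat[:, 1]
    tp_index = cfg.alpha0 + cfg.alpha_age * age + cfg.alpha_kdpi * kdpi + cfg.alpha_epts * epts
    tp = (tp_index + xi > 0).astype(int)
    ystar = (cfg.beta0 + beta1 * tp + cfg.beta_kdpi * kdpi + cfg.beta_age * age
             + cfg.beta_epts * epts + eps)
    df = pd.DataFrame({
        "age": age, "kdpi": kdpi, "epts": epts,
        "tp": tp, "survival_1yr": (ystar > 0).astype(int),
    })
    params = {
        "alpha": {"const": cfg.alpha0, "age": cfg.alpha_age, "kdpi": cfg.alpha_kdpi,
                  "epts": cfg.alpha_epts},
        "beta": {"const": cfg.beta0, "tp": beta1, "kdpi": cfg.beta_kdpi,
                 "age": cfg.beta_age, "epts": cfg.beta_epts},
        "rho": rho,
    }
    return df, params
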