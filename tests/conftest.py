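import numpy as np
import pandas as pd
import pytest

import kidneytp as ktp


def clean_config(**overrides) -> ktp.SimConfig:
    """Generator conditions with no injected artifacts and no timestamp
    jitter, so labeling can be checked against ground truth exactly."""
    base = dict(
        n_donors=250, n_candidates=2500, seed=42,
        bypass_rate=0.0, pediatric_donor_rate=0.0, pediatric_candidate_rate=0.0,
        open_offer_rate=0.0, dual_kidney_rate=0.0, multi_organ_rate=0.0,
        jitter_sd_min=0.0,
    )
    base.update(overrides)
    return ktp.SimConfig(**base)


@pytest.fixture(scope="session")
def clean_sim():
    cfg = clean_config()
    cohort, truth = ktp.simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def labeled_sim(clean_sim):
    cohort, truth = clean_sim
    prepped = ktp.apply_prep_pipeline(ktp.normalize_responses(cohort))
    labels, events = ktp.label_cohort(prepped)
    return prepped, truth, labels, events


@pytest.fixture(scope="session")
def noisy_sim():
    """Cohort with bypass/pediatric/open-offer/dual/multi artifacts injected."""
    cfg = ktp.SimConfig(n_donors=200, n_candidates=2000, seed=7)
    cohort, truth = ktp.simulate_cohort(cfg)
    return cohort, truth


def make_group(rows, match_run_id="MR1", donor_id="D1", txp_id="T1"):
    """Build a program response group from (seq, ptr, init, init_t, fin, fin_t)."""
    recs = []
    for seq, ptr, init, init_t, fin, fin_t in rows:
        recs.append({
            "match_run_id": match_run_id, "donor_id": donor_id, "txp_id": txp_id,
            "ptr_id": ptr, "sequence_number": seq,
            "initial_response": init,
            "initial_response_time": pd.Timestamp(init_t) if init_t else pd.NaT,
            "final_response": fin,
            "final_response_time": pd.Timestamp(fin_t) if fin_t else pd.NaT,
        })
    return pd.DataFrame(recs)
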