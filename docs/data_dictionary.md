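# Data dictionary

Four delimited (CSV) tables; missing values are empty cells; timestamps are
ISO-8601 at minute resolution (`YYYY-MM-DDTHH:MM`), dates `YYYY-MM-DD`.

## offers.csv — one row per donor–candidate offer on a match run

| column | type | meaning |
|---|---|---|
| match_run_id | id | one donor kidney's priority-ordered candidate list |
| donor_id | id | donor |
| ptr_id | id | candidate (potential transplant recipient) |
| txp_id | id | transplant program holding the candidate |
| sequence_number | int >= 1 | priority rank within the match run (1 = highest) |
| initial_response | Y/N/Z/B or empty | program's initial decision |
| initial_response_time | timestamp | when the initial decision was entered |
| final_response | Y/N/Z/B or empty | final decision |
| final_response_time | timestamp | >= initial_response_time when both present |
| notify_time | timestamp or empty | offer notification (mostly missing) |
| refusal_code | code or free text | decline reason (e.g. 801) |
| open_offer | bool | placement made through an open offer |

`(match_run_id, ptr_id)` and `(match_run_id, sequence_number)` are unique.

## donors.csv

donor_id; kdpi in [0,1]; age (years); race; diabetes (0/1); creatinine
(mg/dL); cause_of_death.

## candidates.csv

ptr_id; txp_id; dsa_id (the program's donation service area); epts in [0,1];
age_at_listing (years); sex; race; listing_date.

## transplants.csv — one row per transplanted kidney

donor_id; ptr_id; txp_id; transplant_date; cit_hours (cold ischemia, >= 0);
time_to_transplant (years from listing); survival_1yr (0/1, patient AND graft
at one year); dual_kidney (bool); multi_organ (bool).

## ground_truth.csv (simulated cohorts only)

donor_id; ptr_id; match_run_id; true_tp (0/1); rule_id (0–3); xi, eps (latent
errors); rec_age; kdpi; epts.  `ground_truth_btd.csv` lists the true batch
members as (match_run_id, ptr_id).
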