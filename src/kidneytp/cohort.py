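"""Domain containers for match-run (offer-level) and registry data.

An observation is a donor--candidate specific kidney offer on a match run:
the priority-ordered candidate list an organ procurement organization (OPO)
generates for one donor's kidneys.  Transplant programs respond per candidate
with coded decisions — ``Y`` (accept), ``N`` (decline), ``Z`` (provisional
yes) or ``B`` (OPO bypass) — each carrying an initial and a final timestamp
at minute resolution.  Registry tables carry donor quality (KDPI), candidate
longevity (EPTS), demographics, transplant dates, cold ischemia time and the
binary 1-year patient-and-graft survival outcome.

All tables are plain :class:`pandas.DataFrame` objects with documented
columns (see ``docs/data_dictionary.md``); the :class:`Cohort` dataclass
bundles them with a provenance log of per-step record counts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

RESPONSE_CODES = frozenset({"Y", "N", "Z", "B"})

#: minute-resolution ISO-8601, the serialization format for all timestamps
TIME_FORMAT = "%Y-%m-%dT%H:%M"
DATE_FORMAT = "%Y-%m-%d"

OFFER_COLUMNS = {
    "match_run_id": str,
    "donor_id": str,
    "ptr_id": str,
    "txp_id": str,
    "sequence_number": "Int64",
    "initial_response": str,
    "initial_response_time": "datetime",
    "final_response": str,
    "final_response_time": "datetime",
    "notify_time": "datetime",
    "refusal_code": str,
    "open_offer": bool,
}

DONOR_COLUMNS = {
    "donor_id": str,
    "kdpi": float,
    "age": float,
    "race": str,
    "diabetes": "Int64",
    "creatinine": float,
    "cause_of_death": str,
}

CANDIDATE_COLUMNS = {
    "ptr_id": str,
    "txp_id": str,
    "dsa_id": str,
    "epts": float,
    "age_at_listing": float,
    "sex": str,
    "race": str,
    "listing_date": "date",
}

TRANSPLANT_COLUMNS = {
    "donor_id": str,
    "ptr_id": str,
    "txp_id": str,
    "transplant_date": "date",
    "cit_hours": float,
    "time_to_transplant": float,
    "survival_1yr": "Int64",
    "dual_kidney": bool,
    "multi_organ": bool,
}

_TABLE_SCHEMAS = {
    "offers": OFFER_COLUMNS,
    "donors": DONOR_COLUMNS,
    "candidates": CANDIDATE_COLUMNS,
    "transplants": TRANSPLANT_COLUMNS,
}


class SchemaError(ValueError):
    """A table is missing mandatory columns or has unparseable values."""


class IntegrityError(ValueError):
    """Referential or uniqueness constraints are violated."""


@dataclasses.dataclass
class Cohort:
    """Offers plus keyed registries plus an ordered provenance log.

    ``provenance_log`` entries are ``(step_name, n_in, n_out)`` tuples over
    the offer table; counts telescope (``n_out`` of step *k* equals ``n_in``
    of step *k+1*).
    """

    offers: pd.DataFrame
    donors: pd.DataFrame
    candidates: pd.DataFrame
    transplants: pd.DataFrame
    provenance_log: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)

    def log_step(self, name: str, n_in: int, n_out: int) -> None:
        self.provenance_log.append((name, int(n_in), int(n_out)))

    def copy(self) -> "Cohort":
        return Cohort(
            self.offers.copy(),
            self.donors.copy(),
            self.candidates.copy(),
            self.transplants.copy(),
            list(self.provenance_log),
        )

    def validate(self) -> None:
        """Check invariants: schema, code alphabet, uniqueness, referential
        integrity, timestamp ordering, provenance telescoping."""
        for name, df in self.tables().items():
            missing = set(_TABLE_SCHEMAS[name]) - set(df.columns)
            if missing:
                raise SchemaError(f"{name}: missing columns {sorted(missing)}")
        off = self.offers
        if len(off):
            dup = off.duplicated(subset=["match_run_id", "ptr_id"])
            if dup.any():
                keys = off.loc[dup, ["match_run_id", "ptr_id"]].iloc[0].tolist()
                raise IntegrityError(
                    f"duplicate (match_run_id, ptr_id) offer key: {tuple(keys)}"
                )
            dup_seq = off.duplicated(subset=["match_run_id", "sequence_number"])
            if dup_seq.any():
                raise IntegrityError("sequence_number not unique within match_run_id")
            bad = ~(off["initial_response"].isna() | off["initial_response"].isin(RESPONSE_CODES))
            bad |= ~(off["final_response"].isna() | off["final_response"].isin(RESPONSE_CODES))
            if bad.any():
                raise SchemaError(
                    f"response codes outside {{Y,N,Z,B}} in {int(bad.sum())} offers"
                )
            both = off["initial_response_time"].notna() & off["final_response_time"].notna()
            if (off.loc[both, "final_response_time"] < off.loc[both, "initial_response_time"]).any():
                raise IntegrityError("final_response_time earlier than initial_response_time")
        if len(self.donors) and ((self.donors["kdpi"] < 0) | (self.donors["kdpi"] > 1)).any():
            raise SchemaError("donor kdpi outside [0, 1]")
        if len(self.candidates) and ((self.candidates["epts"] < 0) | (self.candidates["epts"] > 1)).any():
            raise SchemaError("candidate epts outside [0, 1]")
        tx = self.transplants
        if len(tx):
            dangling = ~tx["donor_id"].isin(self.donors["donor_id"])
            dangling |= ~tx["ptr_id"].isin(self.candidates["ptr_id"])
            if dangling.any():
                ids = tx.loc[dangling, ["donor_id", "ptr_id"]].head(5).to_dict("records")
                raise IntegrityError(f"transplants with unresolved foreign keys: {ids}")
            if (tx["cit_hours"].dropna() < 0).any():
                raise SchemaError("negative cit_hours")
            if not tx["survival_1yr"].dropna().isin([0, 1]).all():
                raise SchemaError("survival_1yr outside {0, 1}")
        for (prev, cur) in zip(self.provenance_log, self.provenance_log[1:]):
            if prev[2] != cur[1]:
                raise IntegrityError(
                    f"provenance log does not telescope: {prev} -> {cur}"
                )

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "offers": self.offers,
            "donors": self.donors,
            "candidates": self.candidates,
            "transplants": self.transplants,
        }


def _empty_table(schema: dict) -> pd.DataFrame:
    data = {}
    for col, kind in schema.items():
        if kind in ("datetime", "date"):
            data[col] = pd.Series(dtype="datetime64[ns]")
        elif kind == "Int64":
            data[col] = pd.Series(dtype="Int64")
        elif kind is bool:
            data[col] = pd.Series(dtype=bool)
        elif kind is float:
            data[col] = pd.Series(dtype=float)
        else:
            data[col] = pd.Series(dtype=object)
    return pd.DataFrame(data)


def empty_cohort() -> Cohort:
    return Cohort(*[_empty_table(_TABLE_SCHEMAS[t]) for t in _TABLE_SCHEMAS])


def _coerce(df: pd.DataFrame, schema: dict, table: str) -> pd.DataFrame:
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{table}: missing mandatory columns {sorted(missing)}")
    out = df.copy()
    for col, kind in schema.items():
        s = out[col]
        try:
            if kind == "datetime":
                out[col] = pd.to_datetime(s, format="ISO8601")
            elif kind == "date":
                out[col] = pd.to_datetime(s, format="ISO8601")
            elif kind == "Int64":
                out[col] = pd.array(pd.to_numeric(s), dtype="Int64")
            elif kind is float:
                out[col] = pd.to_numeric(s).astype(float)
            elif kind is bool:
                if s.dtype == object:
                    out[col] = s.map({"True": True, "False": False, True: True, False: False,
                                      "true": True, "false": False}).fillna(False).astype(bool)
                else:
                    out[col] = s.fillna(False).astype(bool)
            else:
                out[col] = s.astype(object).where(s.notna(), None)
                out[col] = out[col].map(lambda v: None if v is None else str(v))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{table}.{col}: unparseable values ({exc})") from exc
    return out[list(schema)]


def read_tables(directory: str | Path) -> Cohort:
    """Read the four CSV tables from ``directory`` into a validated Cohort.

    Missing cells are empty cells in the CSV.  Raises :class:`SchemaError`
    on missing mandatory columns and :class:`IntegrityError` on duplicate
    ``(match_run_id, ptr_id)`` offer keys.
    """
    directory = Path(directory)
    frames = {}
    for name, schema in _TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        raw = pd.read_csv(path, dtype=object, keep_default_na=True)
        frames[name] = _coerce(raw, schema, name)
    cohort = Cohort(frames["offers"], frames["donors"], frames["candidates"], frames["transplants"])
    cohort.validate()
    return cohort


def write_tables(cohort: Cohort, directory: str | Path) -> None:
    """Write the Cohort as four CSVs, round-trippable by :func:`read_tables`.

    Timestamps serialize as ISO-8601 at minute resolution; missing values as
    empty cells.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in cohort.tables().items():
        schema = _TABLE_SCHEMAS[name]
        out = df.copy()
        for col, kind in schema.items():
            if kind == "datetime":
                out[col] = out[col].dt.strftime(TIME_FORMAT)
            elif kind == "date":
                out[col] = out[col].dt.strftime(DATE_FORMAT)
        out.to_csv(directory / f"{name}.csv", index=False)


def link_offers(cohort: Cohort) -> pd.DataFrame:
    """Enrich each offer with donor, candidate and (if any) transplant fields.

    One output row per offer; donor covariates are prefixed ``donor_``,
    candidate covariates ``cand_``.  Offers to never-transplanted candidates
    carry NA transplant fields and ``transplanted = False`` (True only for
    the offer row whose candidate received *this* donor's kidney).
    """
    off = cohort.offers
    dangling = off.loc[~off["donor_id"].isin(cohort.donors["donor_id"]), "donor_id"]
    dangling_c = off.loc[~off["ptr_id"].isin(cohort.candidates["ptr_id"]), "ptr_id"]
    if len(dangling) or len(dangling_c):
        bad = sorted(set(dangling))[:5] + sorted(set(dangling_c))[:5]
        raise IntegrityError(f"offers reference unknown ids: {bad}")
    donors = cohort.donors.rename(
        columns={c: f"donor_{c}" for c in cohort.donors.columns if c != "donor_id"}
    )
    cands = cohort.candidates.rename(
        columns={c: f"cand_{c}" for c in cohort.candidates.columns if c not in ("ptr_id", "txp_id")}
    ).drop(columns=["txp_id"])
    merged = off.merge(donors, on="donor_id", how="left", validate="many_to_one")
    merged = merged.merge(cands, on="ptr_id", how="left", validate="many_to_one")
    tx = cohort.transplants.drop(columns=["txp_id"])
    merged = merged.merge(tx, on=["donor_id", "ptr_id"], how="left", validate="many_to_one")
    merged["transplanted"] = merged["transplant_date"].notna()
    assert len(merged) == len(off)
    return merged
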