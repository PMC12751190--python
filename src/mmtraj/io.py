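"""Reading and writing of cohort tables and pipeline outputs.

All tables are comma-separated UTF-8 text with ISO-8601 dates.  Floats in
output tables are written with 10 significant digits so that reruns can be
compared byte-for-byte.

Input tables
------------
conditions.csv : condition_id, name, chronicity        (chronicity in {acute, chronic})
patients.csv   : patient_id, index_date, age_at_index, sex, deprivation_quintile,
                 rurality, end_date, end_reason
events.csv     : patient_id, condition_id, event_date

Unknown-condition events and events whose patient is absent from the patient
table are hard errors: silently dropping either would bias the person-time
disease matrix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHRONICITY_VALUES = ("acute", "chronic")
SEX_VALUES = ("female", "male")
RURALITY_VALUES = ("urban", "town_fringe", "rural")
END_REASONS = ("death", "censored")

#: days per year used to convert calendar intervals to follow-up years
DAYS_PER_YEAR = 365.25

FLOAT_FORMAT = "%.10g"


class CohortError(ValueError):
    """Raised when an input table violates a cohort invariant."""


@dataclass(frozen=True)
class ConditionDef:
    condition_id: str
    name: str
    chronicity: str

    def __post_init__(self) -> None:
        if self.chronicity not in CHRONICITY_VALUES:
            raise CohortError(
                f"condition {self.condition_id!r}: chronicity must be one of "
                f"{CHRONICITY_VALUES}, got {self.chronicity!r}"
            )


@dataclass
class ConditionDictionary:
    """Ordered set of conditions; the column space of the person-time matrix."""

    conditions: list[ConditionDef]
    _by_id: dict[str, ConditionDef] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for c in self.conditions:
            if c.condition_id in self._by_id:
                raise CohortError(f"duplicate condition_id {c.condition_id!r}")
            self._by_id[c.condition_id] = c

    def __len__(self) -> int:
        return len(self.conditions)

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    @property
    def chronic_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions if c.chronicity == "chronic"]

    @property
    def acute_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions if c.chronicity == "acute"]

    def is_chronic(self, condition_id: str) -> bool:
        return self._by_id[condition_id].chronicity == "chronic"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": [c.condition_id for c in self.conditions],
                "name": [c.name for c in self.conditions],
                "chronicity": [c.chronicity for c in self.conditions],
            }
        )


@dataclass
class Cohort:
    """Patient index table plus long-format diagnosis events.

    ``patients`` columns: patient_id, index_date, age_at_index, sex,
    deprivation_quintile, rurality, end_date, end_reason.
    ``events`` columns: patient_id, condition_id, event_date.
    """

    patients: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.patients
        if p["patient_id"].duplicated().any():
            dup = p.loc[p["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise CohortError(f"duplicate patient_id {dup!r}")
        neg = p["end_date"] < p["index_date"]
        if neg.any():
            pid = p.loc[neg, "patient_id"].iloc[0]
            raise CohortError(f"patient {pid!r}: end_date precedes index_date")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def follow_up_years(self) -> pd.Series:
        """Follow-up in (365.25-day) years, indexed by patient_id."""
        days = (self.patients["end_date"] - self.patients["index_date"]).dt.days
        return pd.Series(
            days.to_numpy() / DAYS_PER_YEAR,
            index=self.patients["patient_id"].to_numpy(),
            name="follow_up_years",
        )


def load_condition_dictionary(path: str | Path | None = None) -> ConditionDictionary:
    """Load a condition dictionary from CSV.

    With no path, loads the packaged synthetic default dictionary, which
    mirrors the class balance of the CALIBER-derived condition set used in
    post-MI multimorbidity studies (62 acute and 227 chronic conditions)
    but carries synthetic condition identifiers.
    """
    if path is None:
        ref = resources.files("mmtraj.data").joinpath("default_conditions_synthetic.csv")
        with resources.as_file(ref) as p:
            return load_condition_dictionary(p)
    df = pd.read_csv(path, dtype=str)
    required = {"condition_id", "name", "chronicity"}
    if not required.issubset(df.columns):
        raise CohortError(f"condition dictionary must have columns {sorted(required)}")
    conditions = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.chronicity not in CHRONICITY_VALUES:
            raise CohortError(
                f"row {i + 2} of {path}: unknown chronicity {row.chronicity!r} "
                f"for condition {row.condition_id!r}"
            )
        conditions.append(ConditionDef(row.condition_id, row.name, row.chronicity))
    d = ConditionDictionary(conditions)
    logger.info(
        "loaded condition dictionary: %d acute, %d chronic",
        len(d.acute_ids),
        len(d.chronic_ids),
    )
    return d


def _parse_dates(series: pd.Series, table: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise CohortError(
            f"{table} row {bad + 2}: unparseable {column} {series.iloc[bad]!r}"
        )
    return parsed


def load_cohort(
    events_path: str | Path,
    patients_path: str | Path,
    dictionary: ConditionDictionary,
) -> Cohort:
    """Load and validate a cohort from patients.csv and events.csv."""
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    events = pd.read_csv(events_path, dtype={"patient_id": str, "condition_id": str})

    patients["index_date"] = _parse_dates(patients["index_date"], "patients", "index_date")
    patients["end_date"] = _parse_dates(patients["end_date"], "patients", "end_date")
    events["event_date"] = _parse_dates(events["event_date"], "events", "event_date")
    patients["age_at_index"] = patients["age_at_index"].astype(float)
    patients["deprivation_quintile"] = patients["deprivation_quintile"].astype(np.int64)

    bad_sex = ~patients["sex"].isin(SEX_VALUES)
    if bad_sex.any():
        raise CohortError(f"patients: unknown sex value {patients.loc[bad_sex, 'sex'].iloc[0]!r}")
    bad_rur = ~patients["rurality"].isin(RURALITY_VALUES)
    if bad_rur.any():
        raise CohortError(
            f"patients: unknown rurality value {patients.loc[bad_rur, 'rurality'].iloc[0]!r}"
        )
    bad_end = ~patients["end_reason"].isin(END_REASONS)
    if bad_end.any():
        raise CohortError(
            f"patients: unknown end_reason {patients.loc[bad_end, 'end_reason'].iloc[0]!r}"
        )

    known_patients = set(patients["patient_id"])
    orphan = ~events["patient_id"].isin(known_patients)
    if orphan.any():
        pid = events.loc[orphan, "patient_id"].iloc[0]
        raise CohortError(
            f"events: {int(orphan.sum())} event(s) reference patient(s) absent "
            f"from the patient table (first: {pid!r})"
        )

    unknown = ~events["condition_id"].isin(set(dictionary.ids))
    if unknown.any():
        cid = events.loc[unknown, "condition_id"].iloc[0]
        raise CohortError(
            f"events: {int(unknown.sum())} event(s) reference condition(s) not in "
            f"the dictionary (first: {cid!r})"
        )

    logger.info("loaded cohort: %d patients, %d events", len(patients), len(events))
    return Cohort(patients=patients, events=events)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table in the package's canonical dialect (10-sig-digit floats)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, date_format="%Y-%m-%d")
    return path


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "patients": write_table(cohort.patients, out_dir / "patients.csv"),
        "events": write_table(cohort.events, out_dir / "events.csv"),
    }


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write named result tables to ``out_dir`` and return a manifest.

    ``results`` maps a table name (e.g. ``"H"``, ``"trajectories"``) to a
    DataFrame.  The manifest lists file name and content hash per output so
    rerun identity can be checked cheaply.
    """
    if not results:
        raise CohortError("empty results object: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in results.items():
        if not isinstance(df, pd.DataFrame):
            raise CohortError(f"result {name!r} is not a table")
        path = write_table(df, out_dir / f"{name}.csv")
        rows.append({"name": name, "file": path.name, "sha256": _file_sha256(path)})
    manifest = pd.DataFrame(rows)
    write_table(manifest, out_dir / "manifest.csv")
    return manifest
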