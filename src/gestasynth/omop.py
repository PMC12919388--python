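"""ETL from simulated cohorts to OMOP CDM v5.4 CSV tables.

Seven tables are produced: ``person``, ``location``,
``observation_period``, ``visit_occurrence``, ``condition_occurrence``,
``procedure_occurrence`` and ``death``.  Location rows carry the Colombian
political division: municipality in ``city``, department in ``state``,
``zip`` empty.  Concept ids come from a user-supplied concept map (a
bundled synthetic fixture stands in for the licensed OMOP vocabulary);
unmapped codes fall back to concept id 0 with the source code always
preserved in the ``*_source_value`` column, per CDM convention.

Row ordering is stable (person_id, then event order), so re-exporting the
same cohort is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .demographics import PersonRecord
from .engine import Issue, StateKind

__all__ = [
    "ConceptMap",
    "OmopBundle",
    "load_concept_map",
    "default_concept_map",
    "map_concept",
    "export_cdm",
    "integrity_check",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS: dict[str, list[str]] = {
    "person": [
        "person_id", "gender_concept_id", "year_of_birth", "month_of_birth",
        "day_of_birth", "birth_datetime", "race_concept_id", "ethnicity_concept_id",
        "location_id", "provider_id", "care_site_id", "person_source_value",
        "gender_source_value", "gender_source_concept_id", "race_source_value",
        "race_source_concept_id", "ethnicity_source_value", "ethnicity_source_concept_id",
    ],
    "location": [
        "location_id", "address_1", "address_2", "city", "state", "zip", "county",
        "location_source_value", "country_concept_id", "country_source_value",
        "latitude", "longitude",
    ],
    "observation_period": [
        "observation_period_id", "person_id", "observation_period_start_date",
        "observation_period_end_date", "period_type_concept_id",
    ],
    "visit_occurrence": [
        "visit_occurrence_id", "person_id", "visit_concept_id", "visit_start_date",
        "visit_start_datetime", "visit_end_date", "visit_end_datetime",
        "visit_type_concept_id", "provider_id", "care_site_id", "visit_source_value",
        "visit_source_concept_id", "admitted_from_concept_id",
        "admitted_from_source_value", "discharged_to_concept_id",
        "discharged_to_source_value", "preceding_visit_occurrence_id",
    ],
    "condition_occurrence": [
        "condition_occurrence_id", "person_id", "condition_concept_id",
        "condition_start_date", "condition_start_datetime", "condition_end_date",
        "condition_end_datetime", "condition_type_concept_id",
        "condition_status_concept_id", "stop_reason", "provider_id",
        "visit_occurrence_id", "visit_detail_id", "condition_source_value",
        "condition_source_concept_id", "condition_status_source_value",
    ],
    "procedure_occurrence": [
        "procedure_occurrence_id", "person_id", "procedure_concept_id",
        "procedure_date", "procedure_datetime", "procedure_end_date",
        "procedure_end_datetime", "procedure_type_concept_id", "modifier_concept_id",
        "quantity", "provider_id", "visit_occurrence_id", "visit_detail_id",
        "procedure_source_value", "procedure_source_concept_id",
        "modifier_source_value",
    ],
    "death": [
        "person_id", "death_date", "death_datetime", "death_type_concept_id",
        "cause_concept_id", "cause_source_value", "cause_source_concept_id",
    ],
}

#: CDM type-concept for records derived from an EHR/registry pipeline.
_TYPE_CONCEPT_ID = 32879  # "Registry"


class ConceptMap:
    """(vocabulary, source code) → concept id lookup."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table["vocabulary"] = table["vocabulary"].astype(str)
        table["source_code"] = table["source_code"].astype(str)
        table["concept_id"] = table["concept_id"].astype(int)
        if (table["concept_id"] < 0).any():
            raise ValueError("concept ids must be non-negative")
        keys = list(zip(table["vocabulary"], table["source_code"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (vocabulary, source_code) rows in concept map")
        self.table = table.reset_index(drop=True)
        self._lookup = dict(zip(keys, table["concept_id"]))

    def get(self, vocabulary: str, code: str) -> int:
        return int(self._lookup.get((str(vocabulary), str(code)), 0))


def load_concept_map(path: Union[str, Path]) -> ConceptMap:
    frame = pd.read_csv(path, dtype={"vocabulary": str, "source_code": str})
    expected = {"vocabulary", "source_code", "concept_id"}
    if not expected.issubset(frame.columns):
        raise ValueError(
            f"concept map CSV must have columns {sorted(expected)}, got {list(frame.columns)}"
        )
    return ConceptMap(frame)


def default_concept_map() -> ConceptMap:
    """The bundled synthetic vocabulary stand-in."""
    with resources.as_file(
        resources.files("gestasynth.data").joinpath("synthetic_concept_map.csv")
    ) as path:
        return load_concept_map(path)


def map_concept(concept_map: ConceptMap, vocabulary: str, code: str) -> int:
    """Mapped concept id, or 0 (the CDM fallback) when absent or empty."""
    if not code:
        return 0
    return concept_map.get(vocabulary, code)


@dataclass
class OmopBundle:
    person: pd.DataFrame
    location: pd.DataFrame
    observation_period: pd.DataFrame
    visit_occurrence: pd.DataFrame
    condition_occurrence: pd.DataFrame
    procedure_occurrence: pd.DataFrame
    death: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def write_csv(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(outdir / f"{name}.csv", index=False, lineterminator="\n")


def export_cdm(
    cohort: Sequence[PersonRecord],
    concept_map: ConceptMap,
    outdir: Optional[Union[str, Path]] = None,
) -> OmopBundle:
    """Build CDM v5.4 tables from a simulated cohort; optionally write CSVs.

    One person row per record; one visit_occurrence per Encounter event;
    one condition_occurrence per ConditionOnset event; one
    procedure_occurrence per Procedure event.  Conditions and procedures
    link to the latest visit on or before their date.  The
    observation_period spans each person's first to last event.  The
    simulated encounter/state name is preserved in a source column
    (``admitted_from_source_value`` for visits,
    ``condition_status_source_value`` for conditions,
    ``modifier_source_value`` for procedures) so the pathway detail
    survives the ETL.
    """
    ids = [p.person_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("cohort contains duplicate person ids")

    female_concept = map_concept(concept_map, "GENDER", "F")
    location_ids: dict[tuple[str, str], int] = {}
    location_rows, person_rows, period_rows = [], [], []
    visit_rows, condition_rows, procedure_rows, death_rows = [], [], [], []
    visit_id = condition_id = procedure_id = period_id = 0

    for record in sorted(cohort, key=lambda p: p.person_id):
        loc_key = (record.municipality, record.department)
        if loc_key not in location_ids:
            location_ids[loc_key] = len(location_ids) + 1
            location_rows.append(
                {
                    "location_id": location_ids[loc_key],
                    "address_1": "", "address_2": "",
                    "city": record.municipality,
                    "state": record.department,
                    "zip": "", "county": "",
                    "location_source_value": record.municipality,
                    "country_concept_id": 0,
                    "country_source_value": "CO",
                    "latitude": "", "longitude": "",
                }
            )
        person_rows.append(
            {
                "person_id": record.person_id,
                "gender_concept_id": female_concept,
                "year_of_birth": record.birthdate.year,
                "month_of_birth": record.birthdate.month,
                "day_of_birth": record.birthdate.day,
                "birth_datetime": f"{record.birthdate.isoformat()}T00:00:00",
                "race_concept_id": 0,
                "ethnicity_concept_id": 0,
                "location_id": location_ids[loc_key],
                "provider_id": "", "care_site_id": "",
                "person_source_value": str(record.person_id),
                "gender_source_value": record.sex,
                "gender_source_concept_id": 0,
                "race_source_value": "", "race_source_concept_id": 0,
                "ethnicity_source_value": "", "ethnicity_source_concept_id": 0,
            }
        )
        events = record.events
        if events:
            period_id += 1
            period_rows.append(
                {
                    "observation_period_id": period_id,
                    "person_id": record.person_id,
                    "observation_period_start_date": events[0].date.isoformat(),
                    "observation_period_end_date": max(e.date for e in events).isoformat(),
                    "period_type_concept_id": _TYPE_CONCEPT_ID,
                }
            )
        # visits in log order, so a same-date later visit (e.g. the
        # emergency visit an onset routes into) wins the linkage below
        person_visits: list[tuple[object, int]] = []
        for event in events:
            if event.kind is StateKind.ENCOUNTER:
                visit_id += 1
                person_visits.append((event.date, visit_id))
                code = event.codes[0]
                visit_rows.append(
                    {
                        "visit_occurrence_id": visit_id,
                        "person_id": record.person_id,
                        "visit_concept_id": map_concept(concept_map, code.system, code.code),
                        "visit_start_date": event.date.isoformat(),
                        "visit_start_datetime": f"{event.date.isoformat()}T00:00:00",
                        "visit_end_date": event.date.isoformat(),
                        "visit_end_datetime": f"{event.date.isoformat()}T00:00:00",
                        "visit_type_concept_id": _TYPE_CONCEPT_ID,
                        "provider_id": "", "care_site_id": "",
                        "visit_source_value": code.code,
                        "visit_source_concept_id": 0,
                        "admitted_from_concept_id": 0,
                        "admitted_from_source_value": event.state,
                        "discharged_to_concept_id": 0,
                        "discharged_to_source_value": "",
                        "preceding_visit_occurrence_id": "",
                    }
                )

        def linked_visit(event_date: object) -> object:
            linked: object = ""
            for date, vid in person_visits:
                if date <= event_date:
                    linked = vid
            return linked

        for event in events:
            code = event.codes[0] if event.codes else None
            if event.kind is StateKind.CONDITION_ONSET:
                condition_id += 1
                condition_rows.append(
                    {
                        "condition_occurrence_id": condition_id,
                        "person_id": record.person_id,
                        "condition_concept_id": map_concept(concept_map, code.system, code.code),
                        "condition_start_date": event.date.isoformat(),
                        "condition_start_datetime": f"{event.date.isoformat()}T00:00:00",
                        "condition_end_date": "", "condition_end_datetime": "",
                        "condition_type_concept_id": _TYPE_CONCEPT_ID,
                        "condition_status_concept_id": 0,
                        "stop_reason": "", "provider_id": "",
                        "visit_occurrence_id": linked_visit(event.date),
                        "visit_detail_id": "",
                        "condition_source_value": code.code,
                        "condition_source_concept_id": 0,
                        "condition_status_source_value": event.state,
                    }
                )
            elif event.kind is StateKind.PROCEDURE:
                procedure_id += 1
                procedure_rows.append(
                    {
                        "procedure_occurrence_id": procedure_id,
                        "person_id": record.person_id,
                        "procedure_concept_id": map_concept(concept_map, code.system, code.code),
                        "procedure_date": event.date.isoformat(),
                        "procedure_datetime": f"{event.date.isoformat()}T00:00:00",
                        "procedure_end_date": "", "procedure_end_datetime": "",
                        "procedure_type_concept_id": _TYPE_CONCEPT_ID,
                        "modifier_concept_id": 0,
                        "quantity": 1,
                        "provider_id": "",
                        "visit_occurrence_id": linked_visit(event.date),
                        "visit_detail_id": "",
                        "procedure_source_value": code.code,
                        "procedure_source_concept_id": 0,
                        "modifier_source_value": event.state,
                    }
                )
            elif event.kind is StateKind.DEATH:
                death_rows.append(
                    {
                        "person_id": record.person_id,
                        "death_date": event.date.isoformat(),
                        "death_datetime": f"{event.date.isoformat()}T00:00:00",
                        "death_type_concept_id": _TYPE_CONCEPT_ID,
                        "cause_concept_id": map_concept(concept_map, code.system, code.code)
                        if code else 0,
                        "cause_source_value": code.code if code else "",
                        "cause_source_concept_id": 0,
                    }
                )

    def frame(rows: list[dict], name: str) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=TABLE_COLUMNS[name])

    bundle = OmopBundle(
        person=frame(person_rows, "person"),
        location=frame(location_rows, "location"),
        observation_period=frame(period_rows, "observation_period"),
        visit_occurrence=frame(visit_rows, "visit_occurrence"),
        condition_occurrence=frame(condition_rows, "condition_occurrence"),
        procedure_occurrence=frame(procedure_rows, "procedure_occurrence"),
        death=frame(death_rows, "death"),
    )
    if outdir is not None:
        bundle.write_csv(outdir)
    return bundle


def integrity_check(bundle: OmopBundle) -> list[Issue]:
    """Audit referential integrity; empty list iff the bundle is sound.

    Checks unique person ids, foreign person/location/visit keys, source
    code retention and the generator's all-female contract.
    """
    issues: list[Issue] = []
    person = bundle.person
    person_ids = set(person["person_id"])
    if len(person_ids) != len(person):
        issues.append(Issue("duplicate_person", None, "person_id values are not unique"))
    location_ids = set(bundle.location["location_id"])
    missing_loc = person.loc[~person["location_id"].isin(location_ids), "person_id"]
    if len(missing_loc):
        issues.append(
            Issue("orphan_location", None,
                  f"persons {missing_loc.tolist()} reference missing locations")
        )
    if not (person["gender_source_value"] == "F").all():
        issues.append(Issue("non_female", None, "generator contract: every person is female"))

    for name in ("observation_period", "visit_occurrence", "condition_occurrence",
                 "procedure_occurrence", "death"):
        table = getattr(bundle, name)
        if len(table) == 0:
            continue
        orphans = set(table["person_id"]) - person_ids
        if orphans:
            issues.append(
                Issue("orphan_person", None, f"{name} references unknown person ids {sorted(orphans)}")
            )

    visit_ids = set(bundle.visit_occurrence["visit_occurrence_id"])
    for name, source_col in (
        ("condition_occurrence", "condition_source_value"),
        ("procedure_occurrence", "procedure_source_value"),
    ):
        table = getattr(bundle, name)
        if len(table) == 0:
            continue
        linked = table["visit_occurrence_id"]
        bad = set(linked[linked != ""].tolist()) - visit_ids
        if bad:
            issues.append(
                Issue("orphan_visit", None, f"{name} references unknown visit ids {sorted(bad)}")
            )
        if (table[source_col].astype(str).str.len() == 0).any():
            issues.append(
                Issue("missing_source_value", None, f"{name} rows lack a source code")
            )
    return issues
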