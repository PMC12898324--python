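"""Readers and writers for cohort tables and single-patient records.

Two interchangeable on-disk representations:

* ``csv`` — long format, one row per (patient, record kind): a ``patient``
  row with demographics, then one ``observation`` row per imaging assessment
  and one ``event`` row per management event. Missing optional fields are
  empty cells (never the strings "NaN"/"None"); booleans are ``true/false``;
  comorbidity sets are semicolon-joined; dates ISO-8601.
* ``json`` — one nested object per patient.

Both round-trip losslessly on valid data.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Optional, Union

from pydantic import ValidationError

from .models import Cohort, Comorbidity, CystObservation, ManagementEvent, PatientRecord

logger = logging.getLogger(__name__)

PATIENT_FIELDS = [
    "age_at_index",
    "sex",
    "surgically_fit",
    "limited_life_expectancy",
    "comorbidities",
    "outcome_pdac",
    "outcome_pdac_date",
    "clinical_followup_months",
    "radiological_followup_months",
]
OBSERVATION_FIELDS = [
    "leading_cyst_size",
    "n_cysts",
    "mpd_diameter",
    "mural_nodule_size",
    "mural_nodule_enhancing",
    "wall_thickened",
    "abrupt_duct_change",
    "lymphadenopathy",
    "obstructive_jaundice",
    "ca19_9",
    "acute_pancreatitis_episode",
    "new_onset_diabetes",
    "modality",
]
EVENT_FIELDS = ["event_type"]

CSV_COLUMNS = ["patient_id", "record_kind", "date"] + PATIENT_FIELDS + OBSERVATION_FIELDS + EVENT_FIELDS


class CohortSchemaError(ValueError):
    """Raised when a cohort file violates the schema; carries row numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("cohort validation failed:\n" + "\n".join(problems))


def _cell(value: Any) -> str:
    """Serialize one value to a CSV cell; None becomes the empty cell."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (set, frozenset)):
        return ";".join(sorted(v.value if hasattr(v, "value") else str(v) for v in value))
    if hasattr(value, "value"):  # enums
        return str(value.value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_cell(raw: str) -> Optional[str]:
    return raw if raw != "" else None


def _parse_bool(raw: Optional[str], field: str, row: int) -> Optional[bool]:
    if raw is None:
        return None
    low = raw.strip().lower()
    if low in ("true", "1"):
        return True
    if low in ("false", "0"):
        return False
    raise CohortSchemaError([f"row {row}: field {field!r}: invalid boolean {raw!r}"])


def write_cohort(cohort: Cohort, path: Union[str, Path], format: str = "csv") -> None:
    """Write ``cohort`` to ``path`` with deterministic column order and
    ISO-8601 dates; the output is re-readable losslessly."""
    path = Path(path)
    if format == "csv":
        _write_csv(cohort, path)
    elif format == "json":
        _write_json(cohort, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_csv(cohort: Cohort, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for patient in cohort.patients:
            row = {
                "patient_id": patient.patient_id,
                "record_kind": "patient",
                "date": "",
            }
            for f in PATIENT_FIELDS:
                row[f] = _cell(getattr(patient, f))
            writer.writerow([row.get(c, "") for c in CSV_COLUMNS])
            for obs in patient.observations:
                row = {
                    "patient_id": patient.patient_id,
                    "record_kind": "observation",
                    "date": obs.observation_date.isoformat(),
                }
                for f in OBSERVATION_FIELDS:
                    row[f] = _cell(getattr(obs, f))
                writer.writerow([row.get(c, "") for c in CSV_COLUMNS])
            for event in patient.management_events:
                row = {
                    "patient_id": patient.patient_id,
                    "record_kind": "event",
                    "date": event.event_date.isoformat(),
                    "event_type": _cell(event.event_type),
                }
                writer.writerow([row.get(c, "") for c in CSV_COLUMNS])


def _patient_to_json(patient: PatientRecord) -> dict:
    data = patient.model_dump(mode="json")
    data["comorbidities"] = sorted(data["comorbidities"])
    return data


def _write_json(cohort: Cohort, path: Path) -> None:
    payload = {
        "provenance": cohort.provenance,
        "patients": [_patient_to_json(p) for p in cohort.patients],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_cohort(path: Union[str, Path], format: str = "csv") -> Cohort:
    """Read and validate a cohort file.

    Per-row validation failures are collected and raised together as a
    :class:`CohortSchemaError` naming the offending rows.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "json":
        return _read_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_json(path: Path) -> Cohort:
    payload = json.loads(path.read_text())
    problems: list[str] = []
    patients: list[PatientRecord] = []
    for i, raw in enumerate(payload.get("patients", [])):
        try:
            patients.append(PatientRecord.model_validate(raw))
        except ValidationError as err:
            problems.append(f"patient #{i}: {err.errors()[0]['msg']}")
    if problems:
        raise CohortSchemaError(problems)
    return Cohort(patients=patients, provenance=payload.get("provenance", ""))


def _read_csv(path: Path) -> Cohort:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortSchemaError(["empty file: missing header"])
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortSchemaError([f"missing required columns: {sorted(missing)}"])
        rows = list(reader)

    # group rows by patient, preserving order
    groups: dict[str, list[tuple[int, dict]]] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):  # header is row 1
        pid = row["patient_id"]
        if pid not in groups:
            groups[pid] = []
            order.append(pid)
        groups[pid].append((i, row))

    problems: list[str] = []
    patients: list[PatientRecord] = []
    for pid in order:
        try:
            patients.append(_build_patient(pid, groups[pid]))
        except CohortSchemaError as err:
            problems.extend(err.problems)
        except (ValidationError, ValueError) as err:
            first = err.errors()[0] if isinstance(err, ValidationError) else None
            msg = f"{first['loc']}: {first['msg']}" if first else str(err)
            rownums = [i for i, _ in groups[pid]]
            problems.append(f"patient {pid!r} (rows {rownums[0]}-{rownums[-1]}): {msg}")
    if problems:
        raise CohortSchemaError(problems)
    return Cohort(patients=patients, provenance=str(path))


def _build_patient(pid: str, rows: list[tuple[int, dict]]) -> PatientRecord:
    patient_row = None
    observations: list[CystObservation] = []
    events: list[ManagementEvent] = []
    for rownum, row in rows:
        kind = row["record_kind"]
        if kind == "patient":
            patient_row = (rownum, row)
        elif kind == "observation":
            observations.append(_build_observation(rownum, row))
        elif kind == "event":
            raw = _parse_cell(row["event_type"])
            if raw is None:
                raise CohortSchemaError([f"row {rownum}: event row missing event_type"])
            events.append(
                ManagementEvent(event_date=row["date"], event_type=raw)
            )
        else:
            raise CohortSchemaError(
                [f"row {rownum}: invalid record_kind {kind!r} (expected patient/observation/event)"]
            )
    if patient_row is None:
        raise CohortSchemaError([f"patient {pid!r}: no 'patient' row found"])
    rownum, row = patient_row
    comorb_raw = _parse_cell(row["comorbidities"])
    comorbidities = set(comorb_raw.split(";")) if comorb_raw else set()
    try:
        return PatientRecord(
            patient_id=pid,
            age_at_index=row["age_at_index"],
            sex=row["sex"],
            surgically_fit=_parse_bool(_parse_cell(row["surgically_fit"]), "surgically_fit", rownum),
            limited_life_expectancy=_parse_bool(
                _parse_cell(row["limited_life_expectancy"]), "limited_life_expectancy", rownum
            ),
            comorbidities={Comorbidity(c) for c in comorbidities},
            observations=observations,
            management_events=events,
            outcome_pdac=_parse_bool(_parse_cell(row["outcome_pdac"]), "outcome_pdac", rownum),
            outcome_pdac_date=_parse_cell(row["outcome_pdac_date"]),
            clinical_followup_months=row["clinical_followup_months"],
            radiological_followup_months=row["radiological_followup_months"],
        )
    except ValueError as err:
        if isinstance(err, ValidationError):
            first = err.errors()[0]
            raise CohortSchemaError(
                [f"row {rownum}: field {'.'.join(str(x) for x in first['loc'])}: {first['msg']}"]
            ) from err
        raise


def _build_observation(rownum: int, row: dict) -> CystObservation:
    kwargs: dict[str, Any] = {"observation_date": row["date"]}
    for f in OBSERVATION_FIELDS:
        raw = _parse_cell(row[f])
        if raw is None:
            continue
        if f in (
            "mural_nodule_enhancing",
            "wall_thickened",
            "abrupt_duct_change",
            "lymphadenopathy",
            "obstructive_jaundice",
            "acute_pancreatitis_episode",
            "new_onset_diabetes",
        ):
            kwargs[f] = _parse_bool(raw, f, rownum)
        else:
            kwargs[f] = raw
    try:
        return CystObservation(**kwargs)
    except ValidationError as err:
        first = err.errors()[0]
        raise CohortSchemaError(
            [f"row {rownum}: field {'.'.join(str(x) for x in first['loc'])}: {first['msg']}"]
        ) from err


def read_patient(path: Union[str, Path]) -> PatientRecord:
    """Read a single-patient JSON record."""
    return PatientRecord.model_validate(json.loads(Path(path).read_text()))


def write_patient(patient: PatientRecord, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(_patient_to_json(patient), indent=1, sort_keys=True) + "\n")
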