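"""Readers and writers for the tabular cohort interchange format.

Both CSV (UTF-8, comma separated, mandatory header) and JSON (array of
objects) carry one record per suspected-reaction case with columns named
exactly after the :class:`~delabel.types.PatientHistory` fields.  When
the ground-truth columns (``allergic`` and the mechanism detail columns)
are present, one :class:`~delabel.types.GroundTruth` per row is returned
as well.

Missing information maps onto explicit codes rather than being dropped:
a blank cell in a tri-state question column reads as ``uncertain`` (the
algorithm routes uncertain like no, so absent information can never
silently de-label), a blank factual cell reads as the field's
unknown/unclear code, and blank age or PEN-FAST item cells read as
unknown (``None``).  ``severe_indicators`` is a semicolon-joined flag
list in a single CSV column; the empty string is the empty set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pydantic

from .types import (
    AnaphylaxisSeverity,
    CulpritClass,
    DelayedSubtype,
    GroundTruth,
    Mechanism,
    OnsetLatency,
    PatientHistory,
    RecallInterval,
    ReportedType,
    Route,
    SevereIndicator,
    TriState,
)


class SchemaError(ValueError):
    """The file does not conform to the documented column schema."""


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (bad value, duplicate id...)."""


TRISTATE_COLUMNS = (
    "symptoms_incompatible_with_allergy",
    "rash_in_childhood_no_systemic",
    "prolonged_urticaria_no_systemic",
    "measles_like_exanthema_adult",
)
PENFAST_COLUMNS = (
    "penfast_five_years_or_less",
    "penfast_anaphylaxis_or_angioedema",
    "penfast_severe_cutaneous",
    "penfast_treatment_required",
)

HISTORY_COLUMNS = (
    "case_id",
    *TRISTATE_COLUMNS[:1],
    "onset_latency",
    *TRISTATE_COLUMNS[1:2],
    "age_at_reaction_years",
    *TRISTATE_COLUMNS[2:],
    "severe_indicators",
    "culprit_class",
    "route",
    "recall_interval",
    "reported_type",
    *PENFAST_COLUMNS,
)
TRUTH_COLUMNS = ("allergic", "mechanism", "anaphylaxis_severity", "delayed_subtype")

# blank factual cells resolve to these codes
_BLANK_DEFAULTS = {
    "onset_latency": OnsetLatency.UNKNOWN.value,
    "culprit_class": CulpritClass.UNCLEAR.value,
    "route": Route.UNCLEAR.value,
    "recall_interval": RecallInterval.UNCLEAR.value,
    "reported_type": ReportedType.UNCERTAIN.value,
}


def _parse_bool(cell: str, column: str, row: int) -> Optional[bool]:
    if cell == "":
        return None
    if cell in ("true", "True"):
        return True
    if cell in ("false", "False"):
        return False
    raise CohortValidationError(f"row {row}: column {column!r}: cannot parse boolean {cell!r}")


def _history_from_cells(cells: dict[str, str], row: int) -> PatientHistory:
    data: dict[str, object] = {"case_id": cells["case_id"]}
    for col in TRISTATE_COLUMNS:
        data[col] = cells[col] if cells[col] != "" else TriState.UNCERTAIN.value
    for col, default in _BLANK_DEFAULTS.items():
        data[col] = cells[col] if cells[col] != "" else default
    age = cells["age_at_reaction_years"]
    data["age_at_reaction_years"] = float(age) if age != "" else None
    flags = cells["severe_indicators"]
    data["severe_indicators"] = frozenset(f for f in flags.split(";") if f != "")
    for col in PENFAST_COLUMNS:
        data[col] = _parse_bool(cells[col], col, row)
    try:
        return PatientHistory(**data)
    except pydantic.ValidationError as exc:
        raise CohortValidationError(f"row {row}: {exc}") from exc


def _truth_from_cells(cells: dict[str, str], row: int) -> GroundTruth:
    allergic = _parse_bool(cells["allergic"], "allergic", row)
    if allergic is None:
        raise CohortValidationError(f"row {row}: column 'allergic' must not be blank")
    data = {
        "case_id": cells["case_id"],
        "allergic": allergic,
        "mechanism": cells["mechanism"] or None,
        "anaphylaxis_severity": cells["anaphylaxis_severity"] or None,
        "delayed_subtype": cells["delayed_subtype"] or None,
    }
    try:
        return GroundTruth(**data)
    except pydantic.ValidationError as exc:
        raise CohortValidationError(f"row {row}: {exc}") from exc


def _check_unique_ids(histories: Sequence[PatientHistory]) -> None:
    seen: set[str] = set()
    for h in histories:
        if h.case_id in seen:
            raise CohortValidationError(f"duplicate case_id {h.case_id!r}")
        seen.add(h.case_id)


def _rows_from_file(path: Path, format: str) -> list[dict[str, str]]:
    if format == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        columns = list(frame.columns)
        rows = frame.to_dict(orient="records")
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise SchemaError("JSON cohort must be an array of objects")
        rows = []
        columns = list(raw[0]) if raw else list(HISTORY_COLUMNS)
        for obj in raw:
            cells: dict[str, str] = {}
            for key, value in obj.items():
                if value is None:
                    cells[key] = ""
                elif isinstance(value, bool):
                    cells[key] = "true" if value else "false"
                elif isinstance(value, list):
                    cells[key] = ";".join(str(v) for v in value)
                else:
                    cells[key] = str(value)
            rows.append(cells)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")
    missing = [c for c in HISTORY_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return rows


def read_cohort(
    path: str | Path, format: str = "csv"
) -> tuple[list[PatientHistory], list[GroundTruth]]:
    """Read a cohort file into patient histories and ground truths.

    Returns ``(histories, truths)``; ``truths`` is empty when the file
    carries no ground-truth columns.  Row order is preserved.

    Raises :class:`SchemaError` for a missing mandatory column and
    :class:`CohortValidationError` (with the offending row number) for
    unparseable values or duplicate case ids.
    """
    path = Path(path)
    rows = _rows_from_file(path, format)
    has_truth = bool(rows) and all(c in rows[0] for c in TRUTH_COLUMNS)
    histories: list[PatientHistory] = []
    truths: list[GroundTruth] = []
    for i, cells in enumerate(rows):
        cells = {k: (v if v is not None else "") for k, v in cells.items()}
        for col in TRUTH_COLUMNS:
            cells.setdefault(col, "")
        histories.append(_history_from_cells(cells, i))
        if has_truth:
            truths.append(_truth_from_cells(cells, i))
    _check_unique_ids(histories)
    return histories, truths


def _history_to_cells(h: PatientHistory) -> dict[str, str]:
    def b(v: Optional[bool]) -> str:
        return "" if v is None else ("true" if v else "false")

    return {
        "case_id": h.case_id,
        "symptoms_incompatible_with_allergy": h.symptoms_incompatible_with_allergy.value,
        "onset_latency": h.onset_latency.value,
        "rash_in_childhood_no_systemic": h.rash_in_childhood_no_systemic.value,
        "age_at_reaction_years": ""
        if h.age_at_reaction_years is None
        else repr(h.age_at_reaction_years),
        "prolonged_urticaria_no_systemic": h.prolonged_urticaria_no_systemic.value,
        "measles_like_exanthema_adult": h.measles_like_exanthema_adult.value,
        "severe_indicators": ";".join(sorted(f.value for f in h.severe_indicators)),
        "culprit_class": h.culprit_class.value,
        "route": h.route.value,
        "recall_interval": h.recall_interval.value,
        "reported_type": h.reported_type.value,
        "penfast_five_years_or_less": b(h.penfast_five_years_or_less),
        "penfast_anaphylaxis_or_angioedema": b(h.penfast_anaphylaxis_or_angioedema),
        "penfast_severe_cutaneous": b(h.penfast_severe_cutaneous),
        "penfast_treatment_required": b(h.penfast_treatment_required),
    }


def _truth_to_cells(t: GroundTruth) -> dict[str, str]:
    return {
        "allergic": "true" if t.allergic else "false",
        "mechanism": t.mechanism.value if t.mechanism else "",
        "anaphylaxis_severity": t.anaphylaxis_severity.value if t.anaphylaxis_severity else "",
        "delayed_subtype": t.delayed_subtype.value if t.delayed_subtype else "",
    }


def write_cohort(
    histories: Iterable[PatientHistory],
    truths: Iterable[GroundTruth],
    path: str | Path,
    format: str = "csv",
) -> Path:
    """Write a cohort (losslessly round-trippable via :func:`read_cohort`).

    ``truths`` may be empty; when present it must cover exactly the
    written case ids.
    """
    histories = list(histories)
    truths = list(truths)
    _check_unique_ids(histories)
    truth_by_id = {t.case_id: t for t in truths}
    if truths:
        history_ids = {h.case_id for h in histories}
        unmatched = set(truth_by_id) - history_ids
        if unmatched:
            raise CohortValidationError(
                f"ground truth references unknown case_id(s): {', '.join(sorted(unmatched))}"
            )
        if len(truth_by_id) != len(truths):
            raise CohortValidationError("duplicate case_id in ground truths")

    columns = list(HISTORY_COLUMNS) + (list(TRUTH_COLUMNS) if truths else [])
    rows = []
    for h in histories:
        cells = _history_to_cells(h)
        if truths:
            t = truth_by_id.get(h.case_id)
            if t is None:
                raise CohortValidationError(f"no ground truth for case_id {h.case_id!r}")
            cells.update(_truth_to_cells(t))
        rows.append(cells)

    path = Path(path)
    if format == "csv":
        frame = pd.DataFrame(rows, columns=columns, dtype=str)
        frame.to_csv(path, index=False)
    elif format == "json":
        objects = []
        for h, cells in zip(histories, rows):
            obj: dict[str, object] = dict(cells)
            obj["age_at_reaction_years"] = h.age_at_reaction_years
            obj["severe_indicators"] = sorted(f.value for f in h.severe_indicators)
            for col in PENFAST_COLUMNS:
                obj[col] = getattr(h, col)
            if truths:
                obj["allergic"] = truth_by_id[h.case_id].allergic
                for col in TRUTH_COLUMNS[1:]:
                    obj[col] = obj[col] or None
            with_none = {k: (None if v == "" else v) for k, v in obj.items()}
            objects.append(with_none)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(objects, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")
    return path
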