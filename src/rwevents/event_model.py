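"""Harmonize heterogeneous longitudinal clinical tables into an event stream.

Real-world clinical data arrive as many per-source tables (medications,
imaging reads, pathology, vital status ...), each with its own column names
and time encoding.  This module reads a small *parameter file* that declares,
per table, which column carries the event name, which category the events
belong to, and which columns carry the start/end times, then builds a single
validated event stream indexed by the patient's age at the event.

Times are real-valued **days of age**.  A table may declare its native unit
(``days``, ``months`` or ``years``); values are converted on load using
1 month = 30.4375 days and 1 year = 365.25 days.  Intervals are closed
``[start_age, end_age]``; point events have ``start_age == end_age``.

Rows that fail validation (unparseable or negative times, end before start)
are dropped and counted in a rejection log rather than raising: observational
data are of inconsistent quality and a single bad row must not sink a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: default name of the patient-identifier column in every raw table
DEFAULT_ID_COL = "patient_id"


class EventCategory(str, Enum):
    """Closed set of event categories.

    ``Treatment``, ``Pathology``, ``ClinicalResponse`` and
    ``ImagingAssessment`` are the four user-assignable categories;
    ``Diagnosis``, ``Death`` and ``LastContact`` are reserved anchors used
    when resolving survival start points and censoring times.
    """

    Treatment = "Treatment"
    Pathology = "Pathology"
    ClinicalResponse = "ClinicalResponse"
    ImagingAssessment = "ImagingAssessment"
    Diagnosis = "Diagnosis"
    Death = "Death"
    LastContact = "LastContact"
    Other = "Other"


def _normalize_category(text: str) -> EventCategory:
    key = "".join(ch for ch in text if ch.isalnum()).lower()
    for cat in EventCategory:
        if cat.value.lower() == key:
            return cat
    allowed = ", ".join(c.value for c in EventCategory)
    raise SchemaError(f"unknown event category {text!r}; allowed: {allowed}")


class SchemaError(ValueError):
    """Raised when a parameter file or raw table violates the declared schema."""


@dataclass(frozen=True)
class ParamEntry:
    """Declaration of one raw table in the parameter file."""

    table_id: str
    file_path: str
    event_name_col: str
    category: EventCategory
    start_col: str
    end_col: Optional[str] = None
    detail_cols: tuple[str, ...] = ()
    time_unit: str = "days"

    @property
    def is_point_table(self) -> bool:
        """True when no end column is declared (instantaneous events)."""
        return self.end_col is None


@dataclass(frozen=True)
class ParameterSpec:
    entries: tuple[ParamEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.table_id for e in self.entries]
        dupes = {t for t in ids if ids.count(t) > 1}
        if dupes:
            raise SchemaError(f"duplicate table_id values: {sorted(dupes)}")


@dataclass(frozen=True)
class EventRecord:
    """One harmonized clinical event, indexed by patient age in days."""

    patient_id: str
    event_name: str
    category: EventCategory
    start_age: float
    end_age: float
    source_table: str = ""
    details: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.start_age > self.end_age:
            raise ValueError(
                f"start_age {self.start_age} > end_age {self.end_age}"
            )

    @property
    def is_point(self) -> bool:
        return self.start_age == self.end_age

    def detail(self, key: str, default: Optional[str] = None) -> Optional[str]:
        for k, v in self.details:
            if k == key:
                return v
        return default

    def sort_key(self) -> tuple:
        return (self.start_age, self.end_age, self.event_name)


@dataclass
class Anchors:
    diagnosis_age: Optional[float] = None
    death_age: Optional[float] = None
    last_contact_age: Optional[float] = None


@dataclass
class PatientTimeline:
    """All events of one patient, sorted by (start, end, name)."""

    patient_id: str
    events: list[EventRecord]
    anchors: Anchors = field(default_factory=Anchors)

    def by_category(self, category: EventCategory) -> list[EventRecord]:
        return [e for e in self.events if e.category == category]


@dataclass
class RejectedRow:
    table_id: str
    row_index: int
    reason: str


@dataclass
class CohortSummary:
    """Tabular cohort summary: categorical frequencies and numeric five-number
    summaries, optionally per stratum."""

    n_patients: int
    categorical: dict[str, dict[str, dict[str, int]]]
    numeric: dict[str, dict[str, dict[str, float]]]
    strata: tuple[str, ...]


# ---------------------------------------------------------------------------
# parameter file
# ---------------------------------------------------------------------------

_REQUIRED_PARAM_COLS = ("table_id", "file", "event_name_col", "category", "start_col")
_VALID_UNITS = {"days": 1.0, "months": DAYS_PER_MONTH, "years": DAYS_PER_YEAR}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited text file, sniffing the delimiter from
    the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def parse_parameter_file(path: str | Path) -> ParameterSpec:
    """Parse the parameter file declaring the raw tables.

    Expected columns: ``table_id, file, event_name_col, category, start_col``
    and optionally ``end_col, detail_cols, time_unit``.  ``detail_cols`` is a
    semicolon-joined list.  An empty ``end_col`` marks a point-event table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)
    missing = [c for c in _REQUIRED_PARAM_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter file missing required column(s): {missing}")
    entries = []
    for _, row in df.iterrows():
        end_col = row.get("end_col", "") or None
        detail_raw = row.get("detail_cols", "") or ""
        detail_cols = tuple(c for c in detail_raw.split(";") if c)
        unit = (row.get("time_unit", "") or "days").strip().lower()
        if unit not in _VALID_UNITS:
            raise SchemaError(
                f"unknown time_unit {unit!r}; allowed: {sorted(_VALID_UNITS)}"
            )
        entries.append(
            ParamEntry(
                table_id=row["table_id"],
                file_path=row["file"],
                event_name_col=row["event_name_col"],
                category=_normalize_category(row["category"]),
                start_col=row["start_col"],
                end_col=end_col,
                detail_cols=detail_cols,
                time_unit=unit,
            )
        )
    return ParameterSpec(entries=tuple(entries))


# ---------------------------------------------------------------------------
# event table construction
# ---------------------------------------------------------------------------

def _parse_time(value, factor: float) -> Optional[float]:
    if value is None:
        return None
    s = str(value).strip()
    if not s or s.lower() in {"na", "nan", "none", "null"}:
        return None
    try:
        t = float(s)
    except ValueError:
        return math.nan
    if math.isnan(t):
        return None
    return t * factor


def build_event_table(
    spec: ParameterSpec,
    tables: Mapping[str, pd.DataFrame],
    id_col: str = DEFAULT_ID_COL,
) -> tuple[list[EventRecord], list[RejectedRow]]:
    """Build the harmonized event stream from raw tables.

    Each input row yields one :class:`EventRecord`; rows with unparseable or
    negative times, or an end before their start, are dropped and recorded in
    the returned rejection log, so that::

        len(events) + len(rejections) == total input rows
    """
    events: list[EventRecord] = []
    rejections: list[RejectedRow] = []
    for entry in spec.entries:
        if entry.table_id not in tables:
            raise SchemaError(f"no table supplied for table_id {entry.table_id!r}")
        df = tables[entry.table_id]
        needed = [id_col, entry.event_name_col, entry.start_col]
        if entry.end_col:
            needed.append(entry.end_col)
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise SchemaError(
                f"table {entry.table_id!r} missing column(s): {missing}"
            )
        factor = _VALID_UNITS[entry.time_unit]
        for idx, row in df.iterrows():
            pid = str(row[id_col]).strip()
            if not pid or pid.lower() == "nan":
                rejections.append(RejectedRow(entry.table_id, idx, "empty patient id"))
                continue
            start = _parse_time(row[entry.start_col], factor)
            if start is None or math.isnan(start):
                rejections.append(
                    RejectedRow(entry.table_id, idx, "unparseable start time")
                )
                continue
            if start < 0:
                rejections.append(RejectedRow(entry.table_id, idx, "negative start time"))
                continue
            end = _parse_time(row[entry.end_col], factor) if entry.end_col else None
            if end is not None and math.isnan(end):
                rejections.append(
                    RejectedRow(entry.table_id, idx, "unparseable end time")
                )
                continue
            if end is None:
                end = start  # point event
            if end < start:
                rejections.append(RejectedRow(entry.table_id, idx, "end before start"))
                continue
            details = tuple(
                (c, str(row[c])) for c in entry.detail_cols if c in df.columns
            )
            events.append(
                EventRecord(
                    patient_id=pid,
                    event_name=str(row[entry.event_name_col]),
                    category=entry.category,
                    start_age=start,
                    end_age=end,
                    source_table=entry.table_id,
                    details=details,
                )
            )
    return events, rejections


def build_timelines(events: Sequence[EventRecord]) -> list[PatientTimeline]:
    """Group events into per-patient timelines with survival anchors.

    Anchors come from Diagnosis/Death/LastContact events (earliest Diagnosis,
    earliest Death, latest LastContact).  When no LastContact event exists the
    censoring anchor falls back to the maximum observed ``end_age`` for that
    patient — a conservative last-seen time.
    """
    by_patient: dict[str, list[EventRecord]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    timelines = []
    for pid in sorted(by_patient):
        evs = sorted(by_patient[pid], key=EventRecord.sort_key)
        anchors = Anchors()
        diag = [e.start_age for e in evs if e.category == EventCategory.Diagnosis]
        death = [e.start_age for e in evs if e.category == EventCategory.Death]
        lc = [e.start_age for e in evs if e.category == EventCategory.LastContact]
        if diag:
            anchors.diagnosis_age = min(diag)
        if death:
            anchors.death_age = min(death)
        if lc:
            anchors.last_contact_age = max(lc)
        else:
            anchors.last_contact_age = max(e.end_age for e in evs)
        timelines.append(PatientTimeline(patient_id=pid, events=evs, anchors=anchors))
    return timelines


# ---------------------------------------------------------------------------
# filtering and summaries
# ---------------------------------------------------------------------------

_EVENT_FIELDS = ("patient_id", "event_name", "category", "start_age", "end_age",
                 "source_table")

_RELATIONS = {
    "equals": lambda a, b: a == b,
    "not_equals": lambda a, b: a != b,
    "contains": lambda a, b: str(b).lower() in str(a).lower(),
    "lt": lambda a, b: float(a) < float(b),
    "le": lambda a, b: float(a) <= float(b),
    "gt": lambda a, b: float(a) > float(b),
    "ge": lambda a, b: float(a) >= float(b),
    "in": lambda a, b: a in b,
}


def _event_value(ev: EventRecord, fieldname: str):
    if fieldname in _EVENT_FIELDS:
        v = getattr(ev, fieldname)
        return v.value if isinstance(v, EventCategory) else v
    v = ev.detail(fieldname)
    if v is None:
        avail = list(_EVENT_FIELDS) + sorted({k for k, _ in ev.details})
        raise KeyError(f"unknown field {fieldname!r}; available: {avail}")
    return v


def filter_cohort(
    events: Sequence[EventRecord],
    predicates: Sequence[tuple[str, str, object]],
) -> list[EventRecord]:
    """Patient-level filter: keep all events of every patient who has at
    least one event satisfying *all* predicates.

    Each predicate is ``(field, relation, value)`` where *field* names an
    :class:`EventRecord` field or a detail key and *relation* is one of
    ``equals, not_equals, contains, lt, le, gt, ge, in``.
    """
    if not predicates:
        return list(events)
    for _, rel, _ in predicates:
        if rel not in _RELATIONS:
            raise ValueError(f"unknown relation {rel!r}; allowed: {sorted(_RELATIONS)}")

    def matches(ev: EventRecord) -> bool:
        for fieldname, rel, value in predicates:
            try:
                v = _event_value(ev, fieldname)
            except KeyError:
                if fieldname in _EVENT_FIELDS:
                    raise
                return False  # detail key absent on this event
            if not _RELATIONS[rel](v, value):
                return False
        return True

    # validate field names against the cohort up front
    detail_keys = {k for ev in events for k, _ in ev.details}
    for fieldname, _, _ in predicates:
        if fieldname not in _EVENT_FIELDS and fieldname not in detail_keys:
            avail = list(_EVENT_FIELDS) + sorted(detail_keys)
            raise KeyError(f"unknown field {fieldname!r}; available: {avail}")

    keep = {ev.patient_id for ev in events if matches(ev)}
    return [ev for ev in events if ev.patient_id in keep]


def summarize_cohort(
    timelines: Sequence[PatientTimeline],
    annotations: Optional[pd.DataFrame] = None,
    strata: Optional[str] = None,
    id_col: str = DEFAULT_ID_COL,
) -> CohortSummary:
    """Tabular cohort summary of patient annotations.

    Categorical variables get per-level frequencies (missing counted as its
    own ``"(missing)"`` level, so frequencies always sum to the number of
    patients); numeric variables get min/Q1/median/Q3/max.  With ``strata``
    the summary is computed per stratum of that annotation variable.
    """
    pids = [t.patient_id for t in timelines]
    n = len(pids)
    if annotations is None:
        annotations = pd.DataFrame({id_col: pids})
    if id_col not in annotations.columns:
        raise SchemaError(f"annotations lack the id column {id_col!r}")
    ann = annotations.set_index(id_col).reindex(pids)
    if strata is not None and strata not in ann.columns:
        raise KeyError(f"stratum variable {strata!r} not in annotations")
    if strata is None:
        groups = {"all": ann}
        labels: tuple[str, ...] = ("all",)
    else:
        svals = ann[strata].astype(object).where(ann[strata].notna(), "(missing)")
        labels = tuple(sorted(map(str, svals.unique())))
        groups = {lab: ann[svals.astype(str) == lab] for lab in labels}
    categorical: dict[str, dict[str, dict[str, int]]] = {}
    numeric: dict[str, dict[str, dict[str, float]]] = {}
    for col in ann.columns:
        if pd.api.types.is_numeric_dtype(ann[col]):
            numeric[col] = {}
            for lab, sub in groups.items():
                vals = sub[col].dropna().to_numpy(dtype=float)
                if len(vals) == 0:
                    numeric[col][lab] = {}
                    continue
                q = np.percentile(vals, [0, 25, 50, 75, 100])
                numeric[col][lab] = {
                    "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
                }
        else:
            categorical[col] = {}
            for lab, sub in groups.items():
                filled = sub[col].astype(object).where(sub[col].notna(), "(missing)")
                counts = filled.astype(str).value_counts().to_dict()
                categorical[col][lab] = {str(k): int(v) for k, v in counts.items()}
    return CohortSummary(
        n_patients=n, categorical=categorical, numeric=numeric, strata=labels
    )


# ---------------------------------------------------------------------------
# on-disk harmonized event table
# ---------------------------------------------------------------------------

_EVENT_TSV_COLS = ("patient_id", "event_name", "category", "start_age", "end_age",
                   "source_table", "details")


def _serialize_details(details: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in details)


def _deserialize_details(text: str) -> tuple[tuple[str, str], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        k, _, v = part.partition("=")
        out.append((k, v))
    return tuple(out)


def write_events(events: Sequence[EventRecord], path: str | Path) -> None:
    """Write the harmonized event table as TSV (round-trip safe: float times
    are written with full precision)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EVENT_TSV_COLS) + "\n")
        for ev in events:
            fh.write(
                "\t".join(
                    [
                        ev.patient_id,
                        ev.event_name,
                        ev.category.value,
                        repr(ev.start_age),
                        repr(ev.end_age),
                        ev.source_table,
                        _serialize_details(ev.details),
                    ]
                )
                + "\n"
            )


def read_events(path: str | Path) -> list[EventRecord]:
    """Read a harmonized event table written by :func:`write_events`."""
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EVENT_TSV_COLS:
            raise SchemaError(
                f"unexpected event-table header {header}; expected {list(_EVENT_TSV_COLS)}"
            )
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pid, name, cat, start, end, src, det = parts
            events.append(
                EventRecord(
                    patient_id=pid,
                    event_name=name,
                    category=EventCategory(cat),
                    start_age=float(start),
                    end_age=float(end),
                    source_table=src,
                    details=_deserialize_details(det),
                )
            )
    return events
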