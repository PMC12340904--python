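"""Derive real-world survival endpoints from patient timelines.

Turns timelines plus derived treatment lines into ``(time, event)`` survival
records for three analyses:

=========  =================  ==============================================
analysis   start point        endpoint events
=========  =================  ==============================================
OS         diagnosis          death (censor at last contact)
TTE        a treatment start  next treatment line, toxicity, death
rwPFS      a treatment start  next treatment line, radiological progression
                              or metastasis, pathological recurrence, death
=========  =================  ==============================================

"Change in treatment line" is resolved structurally — the start of line
``k+1`` where the index line is ``k`` — rather than by name matching.
Progression / metastasis / recurrence detection uses configurable
case-insensitive substring patterns over the response-type event categories,
because real-world vocabularies vary by institution ("Progression",
"progressive disease", "PD", ...).

The endpoint is the **earliest** qualifying event strictly after the start
``t0`` (the open lower bound excludes zero follow-up times and immortal-time
artifacts).  Ties at the same time are broken by the order of the configured
event rules; the default order puts Death last so a same-day progression is
recorded as progression.  Patients whose start cannot be resolved, or whose
last contact is not after ``t0``, are excluded with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .event_model import EventCategory, EventRecord, PatientTimeline
from .line_clustering import TreatmentLine


class MatcherKind(str, Enum):
    NextLineStart = "NextLineStart"
    TreatmentChange = "TreatmentChange"  # structural alias used by TTE
    Progression = "Progression"
    Metastasis = "Metastasis"
    PathRecurrence = "PathRecurrence"
    Toxicity = "Toxicity"
    Death = "Death"


_STRUCTURAL = {MatcherKind.NextLineStart, MatcherKind.TreatmentChange}

_DEFAULT_PATTERNS = {
    MatcherKind.Progression: ("progress",),
    MatcherKind.Metastasis: ("metasta",),
    MatcherKind.PathRecurrence: ("recurren",),
    MatcherKind.Toxicity: ("toxic",),
}

_RESPONSE_CATEGORIES = (
    EventCategory.ImagingAssessment,
    EventCategory.Pathology,
    EventCategory.ClinicalResponse,
)


@dataclass(frozen=True)
class EventMatcher:
    """Matches endpoint events by kind, optional name patterns (case-
    insensitive substrings) and an optional category restriction."""

    kind: MatcherKind
    name_patterns: Optional[tuple[str, ...]] = None
    category_filter: Optional[EventCategory] = None

    def patterns(self) -> tuple[str, ...]:
        if self.name_patterns is not None:
            return tuple(p.lower() for p in self.name_patterns)
        return _DEFAULT_PATTERNS.get(self.kind, ())

    def matches_event(self, ev: EventRecord) -> bool:
        if self.kind in _STRUCTURAL:
            return False  # resolved from line structure, not events
        if self.kind == MatcherKind.Death:
            return ev.category == EventCategory.Death
        if self.category_filter is not None:
            if ev.category != self.category_filter:
                return False
        elif ev.category not in _RESPONSE_CATEGORIES:
            return False
        name = ev.event_name.lower()
        return any(p in name for p in self.patterns())


@dataclass(frozen=True)
class StartRule:
    """Start-point rule: ``diagnosis``, ``first_treatment`` (optionally
    restricted to a name set), ``line(k)`` or ``line_regimen(label)``."""

    kind: str  # diagnosis | first_treatment | line | line_regimen
    names: Optional[frozenset[str]] = None  # for first_treatment
    line_index: Optional[int] = None  # for line
    regimen: Optional[str] = None  # for line_regimen

    @staticmethod
    def diagnosis() -> "StartRule":
        return StartRule(kind="diagnosis")

    @staticmethod
    def first_treatment(names: Optional[Sequence[str]] = None) -> "StartRule":
        return StartRule(
            kind="first_treatment",
            names=frozenset(n.lower() for n in names) if names else None,
        )

    @staticmethod
    def line(index: int) -> "StartRule":
        return StartRule(kind="line", line_index=index)

    @staticmethod
    def line_regimen(label: str) -> "StartRule":
        return StartRule(kind="line_regimen", regimen=label.lower())


_ALLOWED_RULES = {
    "OS": {MatcherKind.Death},
    "TTE": {MatcherKind.TreatmentChange, MatcherKind.NextLineStart,
            MatcherKind.Toxicity, MatcherKind.Death},
    "rwPFS": {MatcherKind.NextLineStart, MatcherKind.Progression,
              MatcherKind.Metastasis, MatcherKind.PathRecurrence,
              MatcherKind.Death},
}


class EndpointConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EndpointConfig:
    """Declarative start-point + endpoint specification.

    Censoring is always at last contact.  Use the :func:`os_config`,
    :func:`tte_config` and :func:`rwpfs_config` helpers for the standard
    analyses.
    """

    analysis: str  # OS | TTE | rwPFS
    start_rule: StartRule
    event_rules: tuple[EventMatcher, ...]

    def __post_init__(self) -> None:
        if self.analysis not in _ALLOWED_RULES:
            raise EndpointConfigError(f"unknown analysis {self.analysis!r}")
        if self.analysis == "OS":
            if self.start_rule.kind != "diagnosis":
                raise EndpointConfigError("OS requires start_rule=diagnosis")
            if {m.kind for m in self.event_rules} != {MatcherKind.Death}:
                raise EndpointConfigError("OS requires event_rules={Death}")
        allowed = _ALLOWED_RULES[self.analysis]
        bad = [m.kind for m in self.event_rules if m.kind not in allowed]
        if bad:
            raise EndpointConfigError(
                f"{self.analysis} does not allow endpoint kinds {bad}"
            )
        if not self.event_rules:
            raise EndpointConfigError("at least one event rule is required")


def os_config() -> EndpointConfig:
    """Overall survival: diagnosis → death, censored at last contact."""
    return EndpointConfig(
        analysis="OS",
        start_rule=StartRule.diagnosis(),
        event_rules=(EventMatcher(MatcherKind.Death),),
    )


def tte_config(start_rule: Optional[StartRule] = None) -> EndpointConfig:
    """Time-to-treatment-end: treatment start → next line / toxicity / death."""
    return EndpointConfig(
        analysis="TTE",
        start_rule=start_rule or StartRule.line(1),
        event_rules=(
            EventMatcher(MatcherKind.TreatmentChange),
            EventMatcher(MatcherKind.Toxicity),
            EventMatcher(MatcherKind.Death),
        ),
    )


def rwpfs_config(
    start_rule: Optional[StartRule] = None,
    progression_patterns: Optional[Sequence[str]] = None,
    include_next_line: bool = True,
) -> EndpointConfig:
    """Real-world PFS: treatment start → next line / progression or
    metastasis / pathological recurrence / death."""
    rules: list[EventMatcher] = []
    if include_next_line:
        rules.append(EventMatcher(MatcherKind.NextLineStart))
    pp = tuple(progression_patterns) if progression_patterns else None
    rules += [
        EventMatcher(MatcherKind.Progression, name_patterns=pp),
        EventMatcher(MatcherKind.Metastasis),
        EventMatcher(MatcherKind.PathRecurrence),
        EventMatcher(MatcherKind.Death),
    ]
    return EndpointConfig(
        analysis="rwPFS",
        start_rule=start_rule or StartRule.line(1),
        event_rules=tuple(rules),
    )


@dataclass
class SurvivalRecord:
    """One (time, event) row for survival statistics.

    ``time`` is in days from the resolved start; ``event`` is 1 when an
    endpoint fired, 0 for censoring; ``endpoint_kind`` names the matcher that
    fired or ``"censored"``.
    """

    patient_id: str
    time: float
    event: int
    group: str = ""
    covariates: dict[str, float] = field(default_factory=dict)
    endpoint_kind: str = "censored"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if (self.event == 0) != (self.endpoint_kind == "censored"):
            raise ValueError("event indicator inconsistent with endpoint_kind")


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def _resolve_start(
    timeline: PatientTimeline, lines: Sequence[TreatmentLine], rule: StartRule
) -> tuple[Optional[float], Optional[int], Optional[str]]:
    """Return (t0, index_line, failure_reason); index_line is the 1-based line
    containing/at the start, used to resolve 'next line' endpoints."""
    if rule.kind == "diagnosis":
        t0 = timeline.anchors.diagnosis_age
        if t0 is None:
            return None, None, "no diagnosis event"
        return t0, 0, None
    if rule.kind == "first_treatment":
        cands = [
            e for e in timeline.by_category(EventCategory.Treatment)
            if rule.names is None or e.event_name.strip().lower() in rule.names
        ]
        if not cands:
            return None, None, "no qualifying treatment start"
        t0 = min(e.start_age for e in cands)
        idx = 0
        for ln in lines:
            if ln.line_start <= t0:
                idx = ln.line_index
        return t0, idx, None
    if rule.kind == "line":
        for ln in lines:
            if ln.line_index == rule.line_index:
                return ln.line_start, ln.line_index, None
        return None, None, f"no treatment line {rule.line_index}"
    if rule.kind == "line_regimen":
        for ln in lines:
            if ln.regimen_label == rule.regimen:
                return ln.line_start, ln.line_index, None
        return None, None, f"no line with regimen {rule.regimen!r}"
    return None, None, f"unknown start rule {rule.kind!r}"


def derive_survival(
    timeline: PatientTimeline,
    lines: Sequence[TreatmentLine],
    config: EndpointConfig,
    log: Optional[list] = None,
) -> Optional[SurvivalRecord]:
    """Derive one survival record, or ``None`` (reason appended to *log*).

    The endpoint is the earliest qualifying event strictly after the start;
    with no qualifying event the patient is censored at last contact.
    """
    def excluded(reason: str) -> None:
        if log is not None:
            log.append((timeline.patient_id, reason))

    t0, index_line, reason = _resolve_start(timeline, lines, config.start_rule)
    if t0 is None:
        excluded(reason or "unresolvable start")
        return None

    # (time, rule_order, kind) candidates
    candidates: list[tuple[float, int, MatcherKind]] = []
    for order, matcher in enumerate(config.event_rules):
        if matcher.kind in _STRUCTURAL:
            nxt = index_line + 1 if index_line is not None else 1
            for ln in lines:
                if ln.line_index >= nxt and ln.line_start > t0:
                    candidates.append((ln.line_start, order, matcher.kind))
                    break
            continue
        if matcher.kind == MatcherKind.Death:
            death = timeline.anchors.death_age
            times = [death] if death is not None else []
            times += [
                e.start_age for e in timeline.events
                if e.category == EventCategory.Death
            ]
            times = [t for t in times if t > t0]
            if times:
                candidates.append((min(times), order, matcher.kind))
            continue
        times = [
            e.start_age for e in timeline.events
            if e.start_age > t0 and matcher.matches_event(e)
        ]
        if times:
            candidates.append((min(times), order, matcher.kind))

    if candidates:
        t_event, _, kind = min(candidates)
        return SurvivalRecord(
            patient_id=timeline.patient_id,
            time=t_event - t0,
            event=1,
            endpoint_kind=kind.value,
        )
    last = timeline.anchors.last_contact_age
    if last is None or last <= t0:
        excluded("non-positive follow-up")
        return None
    return SurvivalRecord(
        patient_id=timeline.patient_id, time=last - t0, event=0
    )


Grouping = Union[str, Mapping[str, str], tuple]


def assign_groups(
    records: list[SurvivalRecord],
    lines_by_patient: Optional[Mapping[str, Sequence[TreatmentLine]]] = None,
    grouping: Grouping = "line1_regimen",
    annotations: Optional[pd.DataFrame] = None,
    id_col: str = "patient_id",
    log: Optional[list] = None,
) -> list[SurvivalRecord]:
    """Populate the ``group`` field of survival records.

    *grouping* is ``"line1_regimen"`` (the patient's first-line regimen
    label), ``("annotation", var)`` with *annotations* keyed by patient id,
    or a custom ``{patient_id: group}`` mapping.  Records whose group cannot
    be resolved are dropped and logged.
    """
    def resolve(pid: str) -> Optional[str]:
        if grouping == "line1_regimen":
            if lines_by_patient is None:
                raise EndpointConfigError(
                    "line1_regimen grouping requires lines_by_patient"
                )
            for ln in lines_by_patient.get(pid, []):
                if ln.line_index == 1:
                    return ln.regimen_label
            return None
        if isinstance(grouping, tuple) and grouping[0] == "annotation":
            var = grouping[1]
            if annotations is None or var not in annotations.columns:
                raise EndpointConfigError(
                    f"annotation grouping variable {var!r} unavailable"
                )
            sub = annotations.loc[annotations[id_col] == pid, var]
            if len(sub) == 0 or pd.isna(sub.iloc[0]):
                return None
            return str(sub.iloc[0])
        if isinstance(grouping, Mapping):
            return grouping.get(pid)
        raise EndpointConfigError(f"unknown grouping spec {grouping!r}")

    out = []
    for rec in records:
        g = resolve(rec.patient_id)
        if g is None:
            if log is not None:
                log.append((rec.patient_id, "unresolvable group"))
            continue
        rec.group = g
        out.append(rec)
    return out


def cohort_survival_table(
    timelines: Sequence[PatientTimeline],
    lines_by_patient: Mapping[str, Sequence[TreatmentLine]],
    config: EndpointConfig,
    grouping: Optional[Grouping] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> tuple[list[SurvivalRecord], list[tuple[str, str]]]:
    """Per-patient survival derivation mapped over the cohort.

    Returns the records plus an exclusion log of (patient_id, reason).
    """
    log: list[tuple[str, str]] = []
    records = []
    for tl in timelines:
        rec = derive_survival(tl, lines_by_patient.get(tl.patient_id, []), config, log)
        if rec is not None:
            records.append(rec)
    if grouping is not None:
        records = assign_groups(
            records, lines_by_patient, grouping, annotations, log=log
        )
    return records, log


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a DataFrame (columns patient_id, time_days, event,
    group, endpoint_kind plus one column per covariate)."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "time_days": r.time,
            "event": r.event,
            "group": r.group,
            "endpoint_kind": r.endpoint_kind,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
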