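"""Cluster temporally proximal treatment events into lines of therapy.

A *line of therapy* is the set of agents administered together as one regimen
phase.  Given per-patient treatment events indexed by age in days, events
whose starts fall within a user-defined window are grouped into one line
(the cohort-level "treatment summary cluster").  Two window semantics are
provided:

``anchor`` (default)
    A line is seeded by the earliest unassigned treatment start ``s0`` and
    absorbs every treatment starting at or before ``s0 + window_days``.  This
    matches the common line-of-therapy convention of a fixed induction window.

``gap``
    A treatment joins the current line if it starts within ``window_days`` of
    the line's latest member start; otherwise it opens a new line.  Chains of
    closely spaced starts can thus extend a line indefinitely.

Membership compares **start** times only — treatment start is the clinical
decision point; a long infusion interval does not extend the recruitment
window.  The boundary is inclusive (a start exactly at ``s0 + window`` joins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .event_model import EventCategory, EventRecord, PatientTimeline

#: 3-month clustering window under the 30.4375 days/month convention
THREE_MONTHS_DAYS = 3 * 30.4375


@dataclass(frozen=True)
class ClusterConfig:
    window_days: float = 90.0
    mode: str = "anchor"  # "anchor" | "gap"
    categories_to_cluster: frozenset[EventCategory] = frozenset(
        {EventCategory.Treatment}
    )

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if self.mode not in ("anchor", "gap"):
            raise ValueError(f"unknown clustering mode {self.mode!r}")


@dataclass
class TreatmentLine:
    """One line of therapy: temporally clustered treatment events with a
    canonical regimen label and a 1-based line index."""

    patient_id: str
    line_index: int
    regimen_label: str
    member_events: list[EventRecord]
    line_start: float
    line_end: float

    @property
    def duration_days(self) -> float:
        return self.line_end - self.line_start

    @property
    def agents(self) -> tuple[str, ...]:
        return tuple(self.regimen_label.split("+"))


@dataclass
class EventCluster:
    """Category-generic temporal cluster (patient event summary view)."""

    patient_id: str
    category: EventCategory
    member_events: list[EventRecord]
    cluster_start: float
    cluster_end: float
    summary_label: str


def regimen_label(events: list[EventRecord]) -> str:
    """Canonical regimen label: distinct lower-cased agent names, sorted
    lexicographically, joined by ``+`` (e.g. ``cisplatin+gemcitabine``)."""
    if not events:
        raise ValueError("regimen_label requires at least one event")
    names = sorted({e.event_name.strip().lower() for e in events})
    return "+".join(names)


def _cluster_sorted(events: list[EventRecord], window: float, mode: str
                    ) -> list[list[EventRecord]]:
    """Partition events (already sorted by start) into start-time clusters."""
    groups: list[list[EventRecord]] = []
    if not events:
        return groups
    if mode == "anchor":
        current: list[EventRecord] = [events[0]]
        anchor = events[0].start_age
        for ev in events[1:]:
            if ev.start_age <= anchor + window:
                current.append(ev)
            else:
                groups.append(current)
                current = [ev]
                anchor = ev.start_age
        groups.append(current)
    else:  # gap
        current = [events[0]]
        last_start = events[0].start_age
        for ev in events[1:]:
            if ev.start_age <= last_start + window:
                current.append(ev)
            else:
                groups.append(current)
                current = [ev]
            last_start = ev.start_age
        groups.append(current)
    return groups


def cluster_treatment_lines(
    timeline: PatientTimeline, config: ClusterConfig = ClusterConfig()
) -> list[TreatmentLine]:
    """Derive the patient's lines of therapy.

    Every Treatment event belongs to exactly one line; lines are ordered by
    start and indexed from 1.  The result is deterministic under input
    permutation because the timeline's events are totally ordered.
    """
    treatments = sorted(
        timeline.by_category(EventCategory.Treatment), key=EventRecord.sort_key
    )
    lines = []
    for i, group in enumerate(
        _cluster_sorted(treatments, config.window_days, config.mode), start=1
    ):
        lines.append(
            TreatmentLine(
                patient_id=timeline.patient_id,
                line_index=i,
                regimen_label=regimen_label(group),
                member_events=group,
                line_start=min(e.start_age for e in group),
                line_end=max(e.end_age for e in group),
            )
        )
    return lines


def aggregate_events(
    timeline: PatientTimeline, config: ClusterConfig = ClusterConfig()
) -> list[EventCluster]:
    """Temporal clustering applied independently per requested category.

    Clusters never mix categories; the summary label joins the distinct
    (case-normalized) member names like a regimen label.
    """
    clusters = []
    for category in sorted(config.categories_to_cluster, key=lambda c: c.value):
        evs = sorted(timeline.by_category(category), key=EventRecord.sort_key)
        for group in _cluster_sorted(evs, config.window_days, config.mode):
            clusters.append(
                EventCluster(
                    patient_id=timeline.patient_id,
                    category=category,
                    member_events=group,
                    cluster_start=min(e.start_age for e in group),
                    cluster_end=max(e.end_age for e in group),
                    summary_label="+".join(
                        sorted({e.event_name.strip().lower() for e in group})
                    ),
                )
            )
    return clusters


def cluster_cohort(
    timelines: list[PatientTimeline], config: ClusterConfig = ClusterConfig()
) -> dict[str, list[TreatmentLine]]:
    """Lines of therapy for every patient, keyed by patient id."""
    return {t.patient_id: cluster_treatment_lines(t, config) for t in timelines}


def parse_window(text: str) -> float:
    """Parse a window spec like ``90d``, ``3mo``, ``1y`` or plain days."""
    s = text.strip().lower()
    if s.endswith("mo"):
        return float(s[:-2]) * 30.4375
    if s.endswith("d"):
        return float(s[:-1])
    if s.endswith("y"):
        return float(s[:-1]) * 365.25
    return float(s)
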