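"""Cohort-level derived structures over lines of therapy and timelines.

* Sankey transition graph of regimens across line indices (link widths are
  patient counts),
* agent x line-index heatmap of distinct-patient counts,
* per-regimen treatment-duration summaries and Tukey upper-fence outlier
  flags ("extended regimens"),
* swimmer-plot lanes (one per patient, optionally re-zeroed to each
  patient's first treatment),
* relative-position annotation of one event kind against another (e.g.
  sequencing before / after / concurrent with a drug regimen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .endpoints import EventMatcher
from .event_model import EventCategory, PatientTimeline
from .line_clustering import TreatmentLine


# ---------------------------------------------------------------------------
# Sankey
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SankeyNode:
    line_index: int
    regimen_label: str
    patient_count: int


@dataclass(frozen=True)
class SankeyLink:
    source: tuple[int, str]  # (line_index, regimen_label)
    target: tuple[int, str]
    patient_count: int


@dataclass
class SankeyGraph:
    """Regimen-transition flow graph.

    For every node at line k: ``patient_count`` equals the sum of outgoing
    link counts plus the terminal count (patients with no line k+1).
    """

    nodes: list[SankeyNode]
    links: list[SankeyLink]
    terminal_counts: dict[tuple[int, str], int]

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"line": n.line_index, "regimen": n.regimen_label,
                 "count": n.patient_count}
                for n in self.nodes
            ],
            "links": [
                {"source": list(l.source), "target": list(l.target),
                 "count": l.patient_count}
                for l in self.links
            ],
            "terminals": [
                {"line": k[0], "regimen": k[1], "count": v}
                for k, v in sorted(self.terminal_counts.items())
            ],
        }


def build_sankey(
    lines_by_patient: Mapping[str, Sequence[TreatmentLine]],
    max_lines: int = 3,
    min_node_size: int = 1,
) -> SankeyGraph:
    """Build the regimen-transition Sankey graph up to ``max_lines`` lines.

    Regimens with fewer than ``min_node_size`` patients at a line index are
    collapsed into an ``"other"`` node at that index.  Counts are patients,
    not events.
    """
    if max_lines < 1:
        raise ValueError("max_lines must be >= 1")
    # per-patient regimen path truncated at max_lines
    paths = {}
    for pid, lines in lines_by_patient.items():
        path = [
            ln.regimen_label
            for ln in sorted(lines, key=lambda l: l.line_index)
            if ln.line_index <= max_lines
        ]
        if path:
            paths[pid] = path

    # raw node counts, then collapse small regimens into "other"
    raw_counts: dict[tuple[int, str], int] = {}
    for path in paths.values():
        for k, reg in enumerate(path, start=1):
            raw_counts[(k, reg)] = raw_counts.get((k, reg), 0) + 1
    relabel = {
        key: (key[0], "other") if cnt < min_node_size else key
        for key, cnt in raw_counts.items()
    }

    node_counts: dict[tuple[int, str], int] = {}
    link_counts: dict[tuple[tuple[int, str], tuple[int, str]], int] = {}
    terminal: dict[tuple[int, str], int] = {}
    for path in paths.values():
        keys = [relabel[(k, reg)] for k, reg in enumerate(path, start=1)]
        for key in keys:
            node_counts[key] = node_counts.get(key, 0) + 1
        for src, tgt in zip(keys, keys[1:]):
            link_counts[(src, tgt)] = link_counts.get((src, tgt), 0) + 1
        last = keys[-1]
        terminal[last] = terminal.get(last, 0) + 1

    nodes = [
        SankeyNode(line_index=k, regimen_label=reg, patient_count=cnt)
        for (k, reg), cnt in sorted(node_counts.items())
    ]
    links = [
        SankeyLink(source=s, target=t, patient_count=c)
        for (s, t), c in sorted(link_counts.items())
    ]
    return SankeyGraph(nodes=nodes, links=links, terminal_counts=terminal)


# ---------------------------------------------------------------------------
# heatmap and durations
# ---------------------------------------------------------------------------

@dataclass
class LineHeatmap:
    """Distinct-patient counts of each agent per line index; agents ordered
    by total count descending (ties alphabetical)."""

    matrix: pd.DataFrame  # index: agent, columns: line_index


def line_heatmap(lines_by_patient: Mapping[str, Sequence[TreatmentLine]]) -> LineHeatmap:
    """Cell (agent, k) counts distinct patients whose line k contains the
    agent; a combination line ``a+b`` increments both agents."""
    cells: dict[tuple[str, int], set[str]] = {}
    for pid, lines in lines_by_patient.items():
        for ln in lines:
            for agent in ln.agents:
                cells.setdefault((agent, ln.line_index), set()).add(pid)
    if not cells:
        return LineHeatmap(matrix=pd.DataFrame())
    agents = sorted({a for a, _ in cells})
    line_idx = sorted({k for _, k in cells})
    mat = pd.DataFrame(0, index=agents, columns=line_idx, dtype=int)
    for (agent, k), pids in cells.items():
        mat.loc[agent, k] = len(pids)
    totals = mat.sum(axis=1)
    order = sorted(agents, key=lambda a: (-totals[a], a))
    return LineHeatmap(matrix=mat.loc[order])


def duration_stats(
    lines_by_patient: Mapping[str, Sequence[TreatmentLine]],
    by: str = "regimen_label",
) -> pd.DataFrame:
    """Five-number summaries of line duration (end - start, days) per group.

    ``by`` is ``"regimen_label"`` or ``"line_index"``.  Empty groups are
    absent from the output.
    """
    rows = []
    for lines in lines_by_patient.values():
        for ln in lines:
            rows.append({
                "group": getattr(ln, by),
                "duration": ln.duration_days,
            })
    if not rows:
        return pd.DataFrame(columns=["group", "n", "min", "q1", "median", "q3", "max"])
    df = pd.DataFrame(rows)
    out = []
    for g, sub in df.groupby("group", sort=True):
        q = np.percentile(sub["duration"].to_numpy(), [0, 25, 50, 75, 100])
        out.append({
            "group": g, "n": len(sub),
            "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
        })
    return pd.DataFrame(out)


@dataclass
class OutlierReport:
    flagged: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flagged,
            columns=["patient_id", "line_index", "regimen_label",
                     "duration_days", "group_q3", "group_iqr"],
        )


def flag_duration_outliers(
    lines_by_patient: Mapping[str, Sequence[TreatmentLine]],
    min_group_size: int = 4,
) -> OutlierReport:
    """Flag extended treatment regimens: within each regimen group of at
    least ``min_group_size`` lines, flag durations strictly above the Tukey
    upper fence Q3 + 1.5 * IQR (upper tail only)."""
    by_regimen: dict[str, list[TreatmentLine]] = {}
    for lines in lines_by_patient.values():
        for ln in lines:
            by_regimen.setdefault(ln.regimen_label, []).append(ln)
    flagged = []
    for reg in sorted(by_regimen):
        group = by_regimen[reg]
        if len(group) < min_group_size:
            continue
        durations = np.array([ln.duration_days for ln in group])
        q1, q3 = np.percentile(durations, [25, 75])
        iqr = q3 - q1
        fence = q3 + 1.5 * iqr
        for ln in group:
            if ln.duration_days > fence:
                flagged.append({
                    "patient_id": ln.patient_id,
                    "line_index": ln.line_index,
                    "regimen_label": reg,
                    "duration_days": ln.duration_days,
                    "group_q3": float(q3),
                    "group_iqr": float(iqr),
                })
    return OutlierReport(flagged=flagged)


# ---------------------------------------------------------------------------
# swimmer plot lanes
# ---------------------------------------------------------------------------

@dataclass
class SwimmerLane:
    patient_id: str
    segments: list[tuple[float, float, str, str]]  # (start, end, category, label)
    points: list[tuple[float, str, str]]  # (time, category, label)
    sort_key: float
    stratum: str = ""


def build_swimmer(
    timelines: Sequence[PatientTimeline],
    sort_by: str = "follow_up_length",
    stratum_var: Optional[str] = None,
    annotations: Optional[pd.DataFrame] = None,
    id_col: str = "patient_id",
    rezero_to_first_treatment: bool = False,
) -> list[SwimmerLane]:
    """One lane per patient, sorted for plotting.

    ``sort_by`` is ``first_treatment`` (ascending age at first treatment),
    ``follow_up_length`` (descending follow-up) or ``stratum`` (group by the
    annotation variable, then descending follow-up within).  With
    ``rezero_to_first_treatment`` every lane is shifted so its first
    treatment start sits at time 0 (time-origin alignment); durations are
    unchanged.
    """
    if sort_by not in ("first_treatment", "follow_up_length", "stratum"):
        raise ValueError(f"unknown sort_by {sort_by!r}")
    strata: dict[str, str] = {}
    if stratum_var is not None:
        if annotations is None or stratum_var not in annotations.columns:
            raise KeyError(f"stratum variable {stratum_var!r} not in annotations")
        strata = dict(zip(annotations[id_col].astype(str), annotations[stratum_var].astype(str)))

    lanes = []
    for tl in timelines:
        treats = tl.by_category(EventCategory.Treatment)
        first_tx = min((e.start_age for e in treats), default=None)
        offset = first_tx if (rezero_to_first_treatment and first_tx is not None) else 0.0
        segments = []
        points = []
        for e in tl.events:
            if e.is_point:
                points.append((e.start_age - offset, e.category.value, e.event_name))
            else:
                segments.append(
                    (e.start_age - offset, e.end_age - offset, e.category.value, e.event_name)
                )
        segments.sort(key=lambda s: (s[0], s[1], s[3]))
        points.sort(key=lambda p: (p[0], p[2]))
        follow_up = (tl.anchors.last_contact_age or 0.0) - (
            min((e.start_age for e in tl.events), default=0.0)
        )
        key = first_tx if sort_by == "first_treatment" else follow_up
        lanes.append(
            SwimmerLane(
                patient_id=tl.patient_id,
                segments=segments,
                points=points,
                sort_key=float(key) if key is not None else float("inf"),
                stratum=strata.get(tl.patient_id, ""),
            )
        )
    if sort_by == "first_treatment":
        lanes.sort(key=lambda l: (l.sort_key, l.patient_id))
    elif sort_by == "follow_up_length":
        lanes.sort(key=lambda l: (-l.sort_key, l.patient_id))
    else:
        lanes.sort(key=lambda l: (l.stratum, -l.sort_key, l.patient_id))
    return lanes


# ---------------------------------------------------------------------------
# relative event position
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSelector:
    """Generic event matcher: case-insensitive substring patterns over the
    event name, optionally restricted to a category.  Unlike the endpoint
    matchers this can select any category (e.g. a Treatment or an Other
    'sequencing' event)."""

    name_patterns: tuple[str, ...] = ()
    category_filter: Optional[EventCategory] = None

    def matches_event(self, ev) -> bool:
        if self.category_filter is not None and ev.category != self.category_filter:
            return False
        if not self.name_patterns:
            return True
        name = ev.event_name.lower()
        return any(p.lower() in name for p in self.name_patterns)


def annotate_relative_position(
    timelines: Sequence[PatientTimeline],
    anchor: "EventSelector | EventMatcher",
    target: "EventSelector | EventMatcher",
) -> dict[str, str]:
    """Per-patient position of the target event relative to the anchor event.

    Labels: ``before`` (target ends before the anchor starts), ``after``
    (target starts after the anchor ends), ``concurrent`` (intervals
    overlap), ``anchor-missing`` / ``target-missing``.  The earliest matching
    event of each kind is used.
    """
    out = {}
    for tl in timelines:
        a = next((e for e in tl.events if anchor.matches_event(e)), None)
        t = next((e for e in tl.events if target.matches_event(e)), None)
        if a is None:
            out[tl.patient_id] = "anchor-missing"
        elif t is None:
            out[tl.patient_id] = "target-missing"
        elif t.end_age < a.start_age:
            out[tl.patient_id] = "before"
        elif t.start_age > a.end_age:
            out[tl.patient_id] = "after"
        else:
            out[tl.patient_id] = "concurrent"
    return out
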