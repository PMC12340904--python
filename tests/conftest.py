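import numpy as np
import pytest

from rwevents import (
    Anchors,
    EventCategory,
    EventRecord,
    PatientTimeline,
    SurvivalRecord,
)


def ev(pid, name, cat, start, end=None, details=()):
    return EventRecord(
        patient_id=pid,
        event_name=name,
        category=EventCategory(cat),
        start_age=float(start),
        end_age=float(end if end is not None else start),
        details=tuple(details),
    )


def timeline(pid, events, diagnosis=None, death=None, last_contact=None):
    events = sorted(events, key=EventRecord.sort_key)
    lc = last_contact
    if lc is None and events:
        lc = max(e.end_age for e in events)
    return PatientTimeline(
        patient_id=pid,
        events=events,
        anchors=Anchors(diagnosis_age=diagnosis, death_age=death,
                        last_contact_age=lc),
    )


def surv(pid, time, event, group="", cov=None):
    return SurvivalRecord(
        patient_id=pid,
        time=float(time),
        event=int(event),
        group=group,
        covariates=dict(cov or {}),
        endpoint_kind="Death" if event else "censored",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def make_event():
    return ev


@pytest.fixture
def make_timeline():
    return timeline


@pytest.fixture
def make_record():
    return surv
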