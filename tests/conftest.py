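from datetime import datetime, timedelta, timezone

import pytest

from periwalk.health_export_io import ActivityRecord, RecordKind
from periwalk.synthetic_cohort import generate_cohort

TZ = timezone(timedelta(hours=1))


def ts(day: str, hms: str, tz=TZ) -> datetime:
    return datetime.strptime(f"{day} {hms}", "%Y-%m-%d %H:%M:%S").replace(tzinfo=tz)


def distance_record(day, start, end, meters, pid="P001", source="Phone", tz=TZ):
    return ActivityRecord(
        patient_id=pid,
        record_kind=RecordKind.distance_walking_running,
        start=ts(day, start, tz),
        end=ts(day, end, tz),
        value=meters,
        source_id=source,
    )


def step_record(day, start, end, steps, pid="P001", tz=TZ):
    return ActivityRecord(
        patient_id=pid,
        record_kind=RecordKind.step_count,
        start=ts(day, start, tz),
        end=ts(day, end, tz),
        value=float(steps),
        source_id="Phone",
    )


@pytest.fixture(scope="session")
def full_cohort(tmp_path_factory):
    """41-patient synthetic cohort: (directory, manifest, ground-truth table)."""
    out = tmp_path_factory.mktemp("cohort41")
    manifest, truth = generate_cohort(out, n_patients=41, seed=1234)
    return out, manifest, truth
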