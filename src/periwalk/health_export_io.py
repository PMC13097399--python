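"""Reading and writing the phone health-export XML dialect.

The export format is a single XML document whose root element wraps zero or
more ``<Record>`` elements.  Each record carries a ``type`` (e.g. the
walking/running-distance or step-count identifiers), a ``sourceName``, a
``unit``, a numeric ``value`` and wall-clock ``startDate``/``endDate``
attributes of the form ``YYYY-MM-DD HH:MM:SS +HHMM``.

Parsing converts every accepted record into canonical units exactly once:
distances become meters, step counts stay whole counts.  Everything
downstream of this module assumes canonical units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "RecordKind",
    "ActivityRecord",
    "CohortManifest",
    "ParseResult",
    "parse_health_export",
    "write_health_export",
    "read_manifest",
    "write_manifest",
    "DISTANCE_TYPE",
    "STEP_TYPE",
]


class RecordKind(str, Enum):
    """The two record categories the analysis consumes."""

    distance_walking_running = "distance_walking_running"
    step_count = "step_count"


#: Export-dialect type identifiers.
DISTANCE_TYPE = "HKQuantityTypeIdentifierDistanceWalkingRunning"
STEP_TYPE = "HKQuantityTypeIdentifierStepCount"

_TYPE_TO_KIND = {
    DISTANCE_TYPE: RecordKind.distance_walking_running,
    STEP_TYPE: RecordKind.step_count,
}
_KIND_TO_TYPE = {v: k for k, v in _TYPE_TO_KIND.items()}

#: Accepted distance unit spellings and their factor to meters.
_DISTANCE_UNIT_TO_M = {"m": 1.0, "km": 1000.0, "mi": 1609.344}

_TS_FORMAT = "%Y-%m-%d %H:%M:%S %z"


@dataclass(frozen=True)
class ActivityRecord:
    """One time-stamped sensor record in canonical units.

    ``start``/``end`` are offset-aware instants; the wall-clock component
    (what the phone displayed) drives civil-day assignment downstream.
    Distance values are meters, step values whole counts.
    """

    patient_id: str
    record_kind: RecordKind
    start: datetime
    end: datetime
    value: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.start.tzinfo is None or self.end.tzinfo is None:
            raise ValueError("record timestamps must carry a UTC offset")
        if self.end < self.start:
            raise ValueError(f"record end {self.end} precedes start {self.start}")
        if self.value < 0:
            raise ValueError(f"record value must be non-negative, got {self.value}")
        if self.record_kind is RecordKind.step_count and self.value != int(self.value):
            raise ValueError(f"step counts must be integers, got {self.value}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    def local_start_date(self) -> date:
        """Civil (phone-local) date of the record's start."""
        return self.start.replace(tzinfo=None).date()

    def local_end_date(self) -> date:
        return self.end.replace(tzinfo=None).date()


@dataclass
class CohortManifest:
    """Per-patient bookkeeping: surgery date and export file location."""

    patient_ids: list[str] = field(default_factory=list)
    surgery_dates: dict[str, date] = field(default_factory=dict)
    export_paths: dict[str, Path] = field(default_factory=dict)

    def add(self, patient_id: str, surgery_date: date, export_path: Path | str) -> None:
        if patient_id in self.surgery_dates:
            raise ValueError(f"duplicate patient_id {patient_id!r} in manifest")
        self.patient_ids.append(patient_id)
        self.surgery_dates[patient_id] = surgery_date
        self.export_paths[patient_id] = Path(export_path)

    def __len__(self) -> int:
        return len(self.patient_ids)

    def __iter__(self):
        for pid in self.patient_ids:
            yield pid, self.surgery_dates[pid], self.export_paths[pid]


@dataclass
class ParseResult:
    """Records plus bookkeeping counts from one export file."""

    records: list[ActivityRecord]
    n_rejected: int = 0
    n_skipped_type: int = 0


def _parse_timestamp(text: str) -> datetime:
    return datetime.strptime(text.strip(), _TS_FORMAT)


def parse_health_export(
    path: Path | str,
    patient_id: str = "",
    record_filter: Iterable[RecordKind] | None = None,
    source_filter: Callable[[str], bool] | None = None,
) -> ParseResult:
    """Parse one export XML file into canonical :class:`ActivityRecord` s.

    Parameters
    ----------
    path
        Export XML file.
    patient_id
        Identifier stamped onto every record.
    record_filter
        Record kinds to keep; default both distance and steps.
    source_filter
        Predicate on the ``sourceName`` attribute; default accepts all
        sources.

    Returns
    -------
    ParseResult
        Records sorted by start time, with counts of records rejected
        (bad timestamp, negative value, unknown unit) and of records
        skipped because their type is not mapped.

    Raises
    ------
    ValueError
        If the file is not well-formed XML; the message names the byte
        offset reported by the XML parser.
    """
    wanted = set(record_filter) if record_filter is not None else set(RecordKind)
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed XML in {path}: {exc.msg} "
            f"(line {exc.lineno}, column {exc.position[1]})"
        ) from exc

    records: list[ActivityRecord] = []
    n_rejected = 0
    n_skipped = 0
    for elem in tree.getroot().iter("Record"):
        rtype = elem.get("type", "")
        kind = _TYPE_TO_KIND.get(rtype)
        if kind is None or kind not in wanted:
            n_skipped += 1
            continue
        source = elem.get("sourceName", "")
        if source_filter is not None and not source_filter(source):
            n_skipped += 1
            continue
        unit = elem.get("unit", "")
        try:
            raw = float(elem.get("value", ""))
            start = _parse_timestamp(elem.get("startDate", ""))
            end = _parse_timestamp(elem.get("endDate", ""))
        except (TypeError, ValueError):
            logger.warning("rejected record in %s: unparseable value/timestamp", path)
            n_rejected += 1
            continue
        if kind is RecordKind.distance_walking_running:
            factor = _DISTANCE_UNIT_TO_M.get(unit)
            if factor is None:
                logger.warning("rejected record in %s: unknown distance unit %r", path, unit)
                n_rejected += 1
                continue
            value = raw * factor
        else:
            if unit != "count":
                logger.warning("rejected record in %s: unknown step unit %r", path, unit)
                n_rejected += 1
                continue
            value = float(round(raw))
        if raw < 0 or end < start:
            logger.warning("rejected record in %s: negative value or end<start", path)
            n_rejected += 1
            continue
        records.append(
            ActivityRecord(
                patient_id=patient_id,
                record_kind=kind,
                start=start,
                end=end,
                value=value,
                source_id=source,
            )
        )

    records.sort(key=lambda r: (r.start, r.end, r.record_kind.value, r.value))
    _warn_on_overlapping_sources(records, path)
    return ParseResult(records=records, n_rejected=n_rejected, n_skipped_type=n_skipped)


def _warn_on_overlapping_sources(records: Sequence[ActivityRecord], path: Path) -> None:
    # Two devices logging distance over the same span can double count.
    last_end: datetime | None = None
    last_source: str | None = None
    for rec in records:
        if rec.record_kind is not RecordKind.distance_walking_running:
            continue
        if last_end is not None and rec.start < last_end and rec.source_id != last_source:
            logger.warning(
                "distance records from distinct sources overlap in %s "
                "(%r vs %r); possible double counting",
                path,
                last_source,
                rec.source_id,
            )
            return
        if last_end is None or rec.end > last_end:
            last_end = rec.end
            last_source = rec.source_id
        last_end = max(last_end, rec.end)


def _format_timestamp(dt: datetime) -> str:
    s = dt.strftime("%Y-%m-%d %H:%M:%S %z")
    return s


def write_health_export(records: Sequence[ActivityRecord], path: Path | str) -> Path:
    """Write records as export-dialect XML; round-trips through the parser.

    Values are written with full float precision so that
    ``parse(write(R))`` reproduces ``R`` up to ordering.
    """
    path = Path(path)
    root = etree.Element("HealthData")
    for rec in records:
        if rec.record_kind is RecordKind.distance_walking_running:
            unit, value = "m", repr(float(rec.value))
        else:
            unit, value = "count", str(int(rec.value))
        etree.SubElement(
            root,
            "Record",
            type=_KIND_TO_TYPE[rec.record_kind],
            sourceName=rec.source_id or "Phone",
            unit=unit,
            value=value,
            startDate=_format_timestamp(rec.start),
            endDate=_format_timestamp(rec.end),
        )
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return path


def read_manifest(path: Path | str) -> CohortManifest:
    """Read a cohort manifest CSV (patient_id, surgery_date, export_path).

    Relative export paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "surgery_date", "export_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    manifest = CohortManifest()
    for row in df.itertuples(index=False):
        export = Path(row.export_path)
        if not export.is_absolute():
            export = path.parent / export
        manifest.add(
            str(row.patient_id),
            datetime.strptime(str(row.surgery_date), "%Y-%m-%d").date(),
            export,
        )
    return manifest


def write_manifest(manifest: CohortManifest, path: Path | str) -> Path:
    """Write a manifest CSV; export paths are stored relative to it."""
    import os

    path = Path(path)
    rows = [
        {
            "patient_id": pid,
            "surgery_date": sdate.isoformat(),
            "export_path": os.path.relpath(p, path.parent),
        }
        for pid, sdate, p in manifest
    ]
    pd.DataFrame(rows, columns=["patient_id", "surgery_date", "export_path"]).to_csv(
        path, index=False
    )
    return path


def total_distance_m(records: Iterable[ActivityRecord]) -> float:
    """Sum of canonical distance values (conservation bookkeeping)."""
    return math.fsum(
        r.value for r in records if r.record_kind is RecordKind.distance_walking_running
    )
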