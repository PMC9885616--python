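"""Reading and writing the event CSV dialect, plus within-source dedup.

The CSV schema is UTF-8, comma-delimited, header row:

    record_id,source,event_date,country,location_name,setting,attack_type,
    named_actor,entity_name,meets_definition,is_aggregated_report,description

Booleans are serialised ``true``/``false``; absent values are empty cells.

Within-source duplicates (one real-world event reported twice in the same
list) are detected with the same definite-match rule used for cross-source
linkage: two records in the same country agreeing exactly on at least two
of date, location and name. Groups are maximal under that relation and the
lexicographically smallest record id in each group is kept.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .event_model import EventRecord, SchemaError, normalize_event
from .linkage import DEFAULT_CONFIG, FieldAgreement, LinkageConfig, classify_pair, compare_fields

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "record_id", "source", "event_date", "country", "location_name",
    "setting", "attack_type", "named_actor", "entity_name",
    "meets_definition", "is_aggregated_report", "description",
]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_events(path, source: str, *, warnings: Optional[list] = None) -> list[EventRecord]:
    """Read one source's events, normalising every row.

    Row order is preserved. A missing schema column or a repeated
    record_id raises :class:`SchemaError`. The file's ``source`` column,
    when non-empty, must agree with ``source``.
    """
    path = Path(path)
    records: list[EventRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in EVENT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing required column(s) {missing}")
        for row in reader:
            file_source = (row.get("source") or "").strip()
            if file_source and file_source != source:
                raise SchemaError(
                    f"{path.name}: row {row.get('record_id')!r} has source "
                    f"{file_source!r}, expected {source!r}"
                )
            row = dict(row)
            row["source"] = source
            record = normalize_event(row, warnings=warnings)
            if record.record_id in seen:
                raise SchemaError(f"{path.name}: duplicate record_id {record.record_id!r}")
            seen.add(record.record_id)
            records.append(record)
    logger.info("read %d events from %s (source %s)", len(records), path, source)
    return records


def _serialize(record: EventRecord) -> dict[str, str]:
    if record.date_precision == "day":
        date_text = record.event_date.isoformat()
    elif record.date_precision == "month":
        date_text = record.event_date.strftime("%Y-%m")
    else:
        date_text = ""
    return {
        "record_id": record.record_id,
        "source": record.source,
        "event_date": date_text,
        "country": record.country,
        "location_name": record.location_name or "",
        "setting": record.setting,
        "attack_type": record.attack_type,
        "named_actor": record.named_actor,
        "entity_name": record.entity_name or "",
        "meets_definition": "true" if record.meets_definition else "false",
        "is_aggregated_report": "true" if record.is_aggregated_report else "false",
        "description": record.description or "",
    }


def write_events(events: Sequence[EventRecord], path) -> None:
    """Write events in the package CSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=EVENT_COLUMNS)
        writer.writeheader()
        for record in events:
            writer.writerow(_serialize(record))


def write_exclusions(rows: Iterable[tuple[str, str]], path) -> None:
    """Write an audit CSV of (record_id, reason) exclusions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "reason"])
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# Within-source duplicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicateGroup:
    """A maximal group of same-source records describing one event."""

    record_ids: frozenset[str]
    basis: FieldAgreement

    @property
    def keep_id(self) -> str:
        return min(self.record_ids)

    @property
    def drop_ids(self) -> frozenset[str]:
        return self.record_ids - {self.keep_id}


def find_duplicates(events: Sequence[EventRecord],
                    config: LinkageConfig = DEFAULT_CONFIG) -> list[DuplicateGroup]:
    """Find maximal within-source duplicate groups.

    All events must share one source. Two records are duplicate-linked when
    the cross-source definite rule holds between them (>=2 exact of date /
    location / name within the same country); groups are the connected
    components of that relation, so the result is order-invariant.
    """
    sources = {e.source for e in events}
    if len(sources) > 1:
        raise ValueError(f"events span multiple sources: {sorted(sources)}")

    by_country: dict[str, list[EventRecord]] = {}
    for rec in events:
        by_country.setdefault(rec.country, []).append(rec)

    parent: dict[str, str] = {e.record_id: e.record_id for e in events}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    basis: dict[str, FieldAgreement] = {}
    for block in by_country.values():
        block = sorted(block, key=lambda r: r.record_id)
        for i, a in enumerate(block):
            for b in block[i + 1:]:
                agreement = compare_fields(a, b, config)
                if classify_pair(agreement) == "definite":
                    union(a.record_id, b.record_id)
                    basis.setdefault(min(a.record_id, b.record_id), agreement)

    groups: dict[str, set[str]] = {}
    for rid in parent:
        root = find(rid)
        groups.setdefault(root, set()).add(rid)

    result = [
        DuplicateGroup(record_ids=frozenset(members), basis=basis[min(members)])
        for members in groups.values()
        if len(members) >= 2
    ]
    result.sort(key=lambda g: g.keep_id)
    return result


def remove_duplicates(events: Sequence[EventRecord],
                      groups: Sequence[DuplicateGroup]) -> tuple[list[EventRecord], set[str]]:
    """Drop all but the smallest record id per duplicate group.

    Returns the kept events (input order preserved) and the dropped ids.
    """
    dropped: set[str] = set()
    for group in groups:
        dropped |= group.drop_ids
    if dropped:
        logger.info("removing %d duplicate record(s): %s", len(dropped), sorted(dropped))
    kept = [e for e in events if e.record_id not in dropped]
    return kept, dropped
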