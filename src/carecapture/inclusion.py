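"""Study inclusion criteria: the data-preparation funnel.

Each record receives exactly one outcome. Checks run in a fixed order —
duplicate, country scope, attack definition, aggregated report — and the
first failing check is the recorded reason, so reason codes are
unambiguous and the per-source funnel counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .event_model import CountryRegistry, EventRecord, country_status

REASONS = (
    "ok",
    "duplicate",
    "country_non_whe",
    "country_excluded",
    "definition_not_met",
    "aggregated_report",
)


@dataclass(frozen=True)
class InclusionOutcome:
    record_id: str
    source: str
    included: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.included != (self.reason == "ok"):
            raise ValueError("included must hold exactly when reason is 'ok'")


def _outcome_for(event: EventRecord, registry: CountryRegistry,
                 duplicate_ids: frozenset[str]) -> InclusionOutcome:
    if event.record_id in duplicate_ids:
        reason = "duplicate"
    else:
        status = country_status(event.country, registry)
        if status == "non_whe":
            reason = "country_non_whe"
        elif status == "excluded":
            reason = "country_excluded"
        elif not event.meets_definition:
            reason = "definition_not_met"
        elif event.is_aggregated_report:
            reason = "aggregated_report"
        else:
            reason = "ok"
    return InclusionOutcome(
        record_id=event.record_id,
        source=event.source,
        included=(reason == "ok"),
        reason=reason,
    )


def apply_inclusion(events: Sequence[EventRecord], registry: CountryRegistry,
                    duplicate_ids: Optional[Iterable[str]] = None,
                    ) -> tuple[list[EventRecord], list[InclusionOutcome]]:
    """Partition events into included and excluded with reason codes.

    ``duplicate_ids`` are the record ids dropped by within-source dedup;
    they are tagged here so the funnel accounts for every raw record.
    """
    dup_ids = frozenset(duplicate_ids or ())
    outcomes = [_outcome_for(e, registry, dup_ids) for e in events]
    included = [e for e, o in zip(events, outcomes) if o.included]
    return included, outcomes


def funnel_counts(outcomes: Sequence[InclusionOutcome]) -> pd.DataFrame:
    """Counts by (source, reason), with all reasons present per source.

    Row counts sum to the per-source input size; ``ok`` rows are the
    included events.
    """
    sources = sorted({o.source for o in outcomes})
    table = pd.DataFrame(0, index=sources, columns=list(REASONS), dtype=int)
    for o in outcomes:
        table.loc[o.source, o.reason] += 1
    table.index.name = "source"
    table["total"] = table[list(REASONS)].sum(axis=1)
    return table


def funnel_report(outcomes: Sequence[InclusionOutcome]) -> str:
    """Plain-text funnel mirroring the data-preparation flow."""
    table = funnel_counts(outcomes)
    lines = ["Data preparation funnel", "======================="]
    for source, row in table.iterrows():
        lines.append(f"source {source}: {row['total']} raw records")
        lines.append(f"  - duplicates removed:        {row['duplicate']}")
        lines.append(f"  - outside WHE countries:     {row['country_non_whe']}")
        lines.append(f"  - excluded country (Syria):  {row['country_excluded']}")
        lines.append(f"  - definition not met:        {row['definition_not_met']}")
        lines.append(f"  - aggregated reports:        {row['aggregated_report']}")
        lines.append(f"  = included:                  {row['ok']}")
    return "\n".join(lines)
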