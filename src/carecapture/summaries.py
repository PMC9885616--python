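"""Descriptive comparison outputs for two linked event datasets.

The tables mirror a two-source comparison report: attack-type counts per
source with matched events in parentheses, country coverage through the
inclusion funnel, monthly counts over the union of events, and actor /
location breakdowns. The report mixes denominators deliberately — some
shares are over the 287-style per-source record universe (matches counted
twice), some over the union (matches counted once), some over the unique
events only, and some over matched pairs — so every output states its
denominator explicitly.

Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from .estimation import round_half_up
from .event_model import (
    ATTACK_TYPES,
    CAPITALS,
    CountryRegistry,
    EventRecord,
    country_status,
    normalize_compare_text,
)
from .inclusion import InclusionOutcome
from .linkage import LinkageResult

logger = logging.getLogger(__name__)

ATTACK_TYPE_LABELS = {
    "access_delivery": "Affecting only access to or delivery of health care",
    "ambulance": "Affecting ambulances",
    "facility": "Affecting facilities",
    "personnel": "Affecting medical personnel",
    "patient": "Affecting patients",
}


def _index(events: Sequence[EventRecord]) -> dict[str, EventRecord]:
    return {e.record_id: e for e in events}


def attack_type_table(included_a: Sequence[EventRecord], included_b: Sequence[EventRecord],
                      linkage: LinkageResult) -> pd.DataFrame:
    """Attack-type comparison: per-source counts, matches, and percentages.

    Rows are the five fixed attack categories. ``total`` counts each
    record once per source (matched events therefore appear in both the A
    and B columns); ``matches`` counts matched pairs once, attributed to
    the A-side record's type. A type conflict inside a matched pair is
    tabulated under the A-side type and logged.
    """
    if linkage.pending_possibles:
        raise ValueError("linkage has pending possible matches; adjudicate first")
    index_a, index_b = _index(included_a), _index(included_b)

    counts = pd.DataFrame(0, index=list(ATTACK_TYPES),
                          columns=["A", "B", "matches", "total"], dtype=int)
    for e in included_a:
        counts.loc[e.attack_type, "A"] += 1
    for e in included_b:
        counts.loc[e.attack_type, "B"] += 1
    for rid_a, rid_b in linkage.matched_pairs:
        type_a = index_a[rid_a].attack_type
        type_b = index_b[rid_b].attack_type
        if type_a != type_b:
            logger.warning("matched pair (%s, %s) disagrees on attack_type: %s vs %s; "
                           "tabulated under %s", rid_a, rid_b, type_a, type_b, type_a)
        counts.loc[type_a, "matches"] += 1

    counts["total"] = counts["A"] + counts["B"]
    n_a, n_b = len(included_a), len(included_b)
    n_total = n_a + n_b
    table = counts.copy()
    table["A_pct"] = [round_half_up(100.0 * c / n_a) if n_a else 0.0 for c in counts["A"]]
    table["B_pct"] = [round_half_up(100.0 * c / n_b) if n_b else 0.0 for c in counts["B"]]
    table["total_pct"] = [round_half_up(100.0 * c / n_total) if n_total else 0.0
                          for c in counts["total"]]
    table.index.name = "attack_type"
    table.attrs["denominators"] = {"A": n_a, "B": n_b, "total": n_total,
                                   "matches": linkage.n_matched}
    return table[["A", "A_pct", "B", "B_pct", "total", "matches", "total_pct"]]


def country_table(events_a: Sequence[EventRecord], events_b: Sequence[EventRecord],
                  outcomes: Sequence[InclusionOutcome],
                  registry: Optional[CountryRegistry] = None) -> pd.DataFrame:
    """Country coverage through the inclusion funnel, per source.

    Rows: countries with any reported event (the excluded country, Syria,
    not counted), countries dropped by the WHE scope filter, countries
    additionally dropped because none of their in-scope events met the
    attack definition, and countries remaining in the final dataset.
    """
    registry = registry or CountryRegistry.whe_2016()
    outcome_by_id = {o.record_id: o for o in outcomes}
    rows = {}
    for source, events in (("A", events_a), ("B", events_b)):
        reported = {e.country for e in events} - registry.excluded
        non_whe = {c for c in reported if country_status(c, registry) == "non_whe"}
        in_scope = reported - non_whe
        final = {e.country for e in events
                 if outcome_by_id[e.record_id].included}
        dropped_definition = in_scope - final
        rows[source] = {
            "countries_with_events": len(reported),
            "excluded_non_whe": len(non_whe),
            "excluded_after_definition": len(dropped_definition),
            "final_included": len(final),
        }
    table = pd.DataFrame(rows)
    table.index.name = "measure"
    return table


def union_events(included_a: Sequence[EventRecord], included_b: Sequence[EventRecord],
                 linkage: LinkageResult) -> list[EventRecord]:
    """The union universe: each matched pair once (A-side record) plus all
    unique events from both sources."""
    if linkage.pending_possibles:
        raise ValueError("linkage has pending possible matches; adjudicate first")
    index_a, index_b = _index(included_a), _index(included_b)
    events = [index_a[rid_a] for rid_a, _ in linkage.matched_pairs]
    events.extend(index_a[rid] for rid in sorted(linkage.unique_a))
    events.extend(index_b[rid] for rid in sorted(linkage.unique_b))
    return events


def monthly_counts(union: Sequence[EventRecord]) -> tuple[pd.Series, int]:
    """Events per calendar month over the union universe.

    Needs at least month precision; returns (12-entry series indexed by
    month number, count of unknown-date events reported separately).
    """
    series = pd.Series(0, index=range(1, 13), dtype=int, name="events")
    series.index.name = "month"
    unknown = 0
    for e in union:
        if e.date_precision == "unknown":
            unknown += 1
        else:
            series[e.event_date.month] += 1
    return series, unknown


def actor_and_location_breakdown(included_a: Sequence[EventRecord],
                                 included_b: Sequence[EventRecord],
                                 linkage: LinkageResult) -> dict:
    """Named-actor tallies and location/setting shares.

    Bases differ by design and are reported alongside each figure:
    matched-pair shares use the number of matched pairs; the unique-event
    actor share uses the count of non-matched events; missing-location and
    setting shares use the per-source record universe (matches counted
    once per source record).
    """
    if linkage.pending_possibles:
        raise ValueError("linkage has pending possible matches; adjudicate first")
    index_a, index_b = _index(included_a), _index(included_b)
    matched_a = [index_a[a] for a, _ in linkage.matched_pairs]
    uniques = [index_a[rid] for rid in sorted(linkage.unique_a)]
    uniques += [index_b[rid] for rid in sorted(linkage.unique_b)]
    all_records = list(included_a) + list(included_b)

    n_matches = len(matched_a)
    n_unique = len(uniques)
    n_records = len(all_records)

    matched_msf = sum(e.named_actor == "msf_redcross" for e in matched_a)
    matched_known = sum(e.named_actor in ("msf_redcross", "other") for e in matched_a)
    unique_msf = sum(e.named_actor == "msf_redcross" for e in uniques)

    missing_a = sum(e.location_name is None for e in included_a)
    missing_b = sum(e.location_name is None for e in included_b)
    urban = sum(e.setting == "urban" for e in all_records)
    rural = sum(e.setting == "rural" for e in all_records)

    capital_matches = 0
    for e in matched_a:
        capital = CAPITALS.get(e.country)
        if capital and e.location_name and \
                normalize_compare_text(e.location_name) == normalize_compare_text(capital):
            capital_matches += 1

    def pct(count: int, base: int) -> float:
        return round_half_up(100.0 * count / base) if base else 0.0

    return {
        "n_matches": n_matches,
        "n_unique_events": n_unique,
        "n_records": n_records,
        "matched_msf_redcross": {"count": matched_msf, "base": n_matches,
                                 "pct": pct(matched_msf, n_matches)},
        "matched_known_actor": {"count": matched_known, "base": n_matches,
                                "pct": pct(matched_known, n_matches)},
        "unique_msf_redcross": {"count": unique_msf, "base": n_unique,
                                "pct": pct(unique_msf, n_unique)},
        "missing_location": {"count": missing_a + missing_b, "base": n_records,
                             "count_a": missing_a, "count_b": missing_b,
                             "pct": pct(missing_a + missing_b, n_records)},
        "urban": {"count": urban, "base": n_records, "pct": pct(urban, n_records)},
        "rural": {"count": rural, "base": n_records, "pct": pct(rural, n_records)},
        "capital_city_matches": {"count": capital_matches, "base": n_matches,
                                 "pct": pct(capital_matches, n_matches)},
    }


def render_report(attack_table: pd.DataFrame, country: pd.DataFrame,
                  monthly: pd.Series, unknown_dates: int, breakdown: dict) -> str:
    """Plain-text comparison report combining the summary outputs."""
    lines: list[str] = []
    lines.append("Type of attack (counts per source; matches counted once)")
    lines.append("-" * 60)
    for attack_type, row in attack_table.iterrows():
        label = ATTACK_TYPE_LABELS.get(attack_type, attack_type)
        lines.append(
            f"{label}: A {int(row['A'])} ({row['A_pct']}%), "
            f"B {int(row['B'])} ({row['B_pct']}%), "
            f"total {int(row['total'])} ({int(row['matches'])}) ({row['total_pct']}%)"
        )
    lines.append("")
    lines.append("Country coverage")
    lines.append("-" * 60)
    lines.append(country.to_string())
    lines.append("")
    lines.append("Monthly counts over the union of events")
    lines.append("-" * 60)
    lines.append(" ".join(f"{m}:{c}" for m, c in monthly.items()))
    if unknown_dates:
        lines.append(f"unknown date: {unknown_dates}")
    lines.append("")
    lines.append("Actors and locations (each share states its base)")
    lines.append("-" * 60)
    for key in ("matched_msf_redcross", "matched_known_actor", "unique_msf_redcross",
                "missing_location", "urban", "rural", "capital_city_matches"):
        entry = breakdown[key]
        lines.append(f"{key}: {entry['count']}/{entry['base']} = {entry['pct']}%")
    return "\n".join(lines)
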