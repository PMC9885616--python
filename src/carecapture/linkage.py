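"""Cross-source record linkage of reported attack events.

Two lists of events describing the same underlying year of attacks are
compared pairwise, within country blocks, on three identifying fields:
the date of the attack, the sub-national location, and the name of the
facility or victim. Each pair is graded per field (exact / approximate /
none / unassessable) and classified:

* **definite** — two or more fields agree exactly;
* **possible** — weaker but non-empty agreement (at least one approximate
  field, or exactly one exact field); resolved by an adjudicator, which in
  synthetic mode is the ground-truth key and in real mode a human review
  file;
* **unique** — no usable agreement.

Definite pairs are resolved to a one-to-one matching greedily, best
agreement first, with deterministic tie-breaks so the result is invariant
to input row order and to swapping the two lists.
"""

from __future__ import annotations

import csv
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .event_model import EventRecord, normalize_compare_text

# ---------------------------------------------------------------------------
# String similarity
# ---------------------------------------------------------------------------

def jaro_similarity(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1]."""
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    match_window = max(len1, len2) // 2 - 1
    if match_window < 0:
        match_window = 0
    flags1 = [False] * len1
    flags2 = [False] * len2
    matches = 0
    for i, ch in enumerate(s1):
        lo = max(0, i - match_window)
        hi = min(len2, i + match_window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == ch:
                flags1[i] = flags2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    transpositions = 0
    k = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[k]:
                k += 1
            if s1[i] != s2[k]:
                transpositions += 1
            k += 1
    t = transpositions // 2
    m = matches
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1) -> float:
    """Jaro-Winkler similarity: Jaro with a bonus for a common prefix."""
    jaro = jaro_similarity(s1, s2)
    prefix = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        prefix += 1
    return jaro + prefix * prefix_scale * (1.0 - jaro)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageConfig:
    """Tolerances for field comparison.

    ``date_tolerance_days`` bounds the day gap still graded approximate;
    the string thresholds are Jaro-Winkler similarities on case-folded,
    diacritic-stripped, whitespace-collapsed text.
    """

    date_tolerance_days: int = 2
    location_threshold: float = 0.90
    name_threshold: float = 0.90


DEFAULT_CONFIG = LinkageConfig()


# ---------------------------------------------------------------------------
# Field agreement
# ---------------------------------------------------------------------------

GRADES = ("exact", "approximate", "none", "unassessable")

_CREDIT = {"exact": 1.0, "approximate": 0.5, "none": 0.0, "unassessable": 0.0}


@dataclass(frozen=True)
class FieldAgreement:
    """Per-pair agreement vector over date, location and name."""

    date_cmp: str
    location_cmp: str
    name_cmp: str
    location_score: Optional[float] = None
    name_score: Optional[float] = None
    date_gap_days: Optional[int] = None

    @property
    def grades(self) -> tuple[str, str, str]:
        return (self.date_cmp, self.location_cmp, self.name_cmp)

    @property
    def n_exact(self) -> int:
        return sum(g == "exact" for g in self.grades)

    @property
    def n_approximate(self) -> int:
        return sum(g == "approximate" for g in self.grades)

    @property
    def score(self) -> float:
        return sum(_CREDIT[g] for g in self.grades)


def _compare_dates(a: EventRecord, b: EventRecord, config: LinkageConfig) -> tuple[str, Optional[int]]:
    if a.date_precision == "unknown" or b.date_precision == "unknown":
        return "unassessable", None
    if a.date_precision == "day" and b.date_precision == "day":
        gap = abs((a.event_date - b.event_date).days)
        if gap == 0:
            return "exact", 0
        if gap <= config.date_tolerance_days:
            return "approximate", gap
        return "none", gap
    # At least one side is month precision: same calendar month is exact
    # only when both are month precision, otherwise merely approximate.
    same_month = (a.event_date.year, a.event_date.month) == (b.event_date.year, b.event_date.month)
    if not same_month:
        return "none", None
    if a.date_precision == "month" and b.date_precision == "month":
        return "exact", None
    return "approximate", None


def _compare_text(a: Optional[str], b: Optional[str], threshold: float) -> tuple[str, Optional[float]]:
    if a is None or b is None:
        return "unassessable", None
    na, nb = normalize_compare_text(a), normalize_compare_text(b)
    score = jaro_winkler(na, nb)
    if na == nb:
        return "exact", score
    if score >= threshold:
        return "approximate", score
    return "none", score


def compare_fields(a: EventRecord, b: EventRecord, config: LinkageConfig = DEFAULT_CONFIG) -> FieldAgreement:
    """Grade agreement of the three identifying fields for one pair."""
    date_cmp, gap = _compare_dates(a, b, config)
    loc_cmp, loc_score = _compare_text(a.location_name, b.location_name, config.location_threshold)
    name_cmp, name_score = _compare_text(a.entity_name, b.entity_name, config.name_threshold)
    return FieldAgreement(
        date_cmp=date_cmp,
        location_cmp=loc_cmp,
        name_cmp=name_cmp,
        location_score=loc_score,
        name_score=name_score,
        date_gap_days=gap,
    )


def classify_pair(agreement: FieldAgreement) -> str:
    """Three-way pair status from a field-agreement vector.

    Definite requires two or more exact fields; anything weaker but
    non-empty (any approximate field, or a single exact field) is only a
    possible match, left for adjudication; otherwise unique. Unassessable
    fields never count toward agreement.
    """
    if agreement.n_exact >= 2:
        return "definite"
    if agreement.n_approximate >= 1 or agreement.n_exact == 1:
        return "possible"
    return "unique"


@dataclass(frozen=True)
class MatchDecision:
    """A graded candidate pair."""

    record_id_a: str
    record_id_b: str
    agreement: FieldAgreement
    status: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.record_id_a, self.record_id_b)

    @property
    def score(self) -> float:
        return self.agreement.score


@dataclass
class LinkageResult:
    """One-to-one matches plus per-source unique events.

    ``pending_possibles`` is empty after adjudication; when no adjudicator
    is available the possible pairs are kept pending and their records are
    withheld from the unique sets.
    """

    matched_pairs: list[tuple[str, str]] = field(default_factory=list)
    unique_a: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)
    pending_possibles: list[MatchDecision] = field(default_factory=list)
    decisions: dict[tuple[str, str], MatchDecision] = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _pair_sort_key(decision: MatchDecision) -> tuple:
    gap = decision.agreement.date_gap_days
    return (
        -decision.score,
        gap if gap is not None else 10 ** 6,
        tuple(sorted(decision.pair)),
    )


def _greedy_one_to_one(decisions: Sequence[MatchDecision],
                       taken_a: set[str], taken_b: set[str]) -> list[tuple[str, str]]:
    chosen: list[tuple[str, str]] = []
    for d in sorted(decisions, key=_pair_sort_key):
        if d.record_id_a in taken_a or d.record_id_b in taken_b:
            continue
        taken_a.add(d.record_id_a)
        taken_b.add(d.record_id_b)
        chosen.append(d.pair)
    return chosen


Adjudicator = Callable[[Sequence[MatchDecision]], Mapping[tuple[str, str], str]]


def truth_key_adjudicator(truth_pairs: Iterable[tuple[str, str]]) -> Adjudicator:
    """Adjudicator that resolves possibles against a ground-truth key."""
    truth = set(truth_pairs)

    def adjudicate(pending: Sequence[MatchDecision]) -> dict[tuple[str, str], str]:
        return {d.pair: ("definite" if d.pair in truth else "unique") for d in pending}

    return adjudicate


def link(events_a: Sequence[EventRecord], events_b: Sequence[EventRecord],
         config: LinkageConfig = DEFAULT_CONFIG,
         adjudicator: Optional[Adjudicator] = None) -> LinkageResult:
    """Link two event lists into a one-to-one matching.

    Candidate pairs are generated only within identical-country blocks.
    Definite pairs are assigned greedily (score descending, date gap
    ascending, then lexicographic id pair); possible pairs among the
    remaining records go to the adjudicator. Without an adjudicator the
    possibles stay pending and a warning is issued.
    """
    by_country_b: dict[str, list[EventRecord]] = {}
    for rec in events_b:
        by_country_b.setdefault(rec.country, []).append(rec)

    definites: list[MatchDecision] = []
    possibles: list[MatchDecision] = []
    all_decisions: dict[tuple[str, str], MatchDecision] = {}
    for rec_a in events_a:
        for rec_b in by_country_b.get(rec_a.country, ()):
            agreement = compare_fields(rec_a, rec_b, config)
            status = classify_pair(agreement)
            if status == "unique":
                continue
            decision = MatchDecision(rec_a.record_id, rec_b.record_id, agreement, status)
            all_decisions[decision.pair] = decision
            (definites if status == "definite" else possibles).append(decision)

    taken_a: set[str] = set()
    taken_b: set[str] = set()
    matched = _greedy_one_to_one(definites, taken_a, taken_b)

    pending = [d for d in possibles
               if d.record_id_a not in taken_a and d.record_id_b not in taken_b]

    if pending and adjudicator is not None:
        rulings = adjudicator(pending)
        promoted = [d for d in pending if rulings.get(d.pair) == "definite"]
        matched.extend(_greedy_one_to_one(promoted, taken_a, taken_b))
        pending = []
    elif pending:
        _warnings.warn(
            f"{len(pending)} possible matches left unadjudicated; "
            "export them for review with adjudicate_export()",
            stacklevel=2,
        )

    pending_ids_a = {d.record_id_a for d in pending}
    pending_ids_b = {d.record_id_b for d in pending}
    result = LinkageResult(
        matched_pairs=sorted(matched),
        unique_a={r.record_id for r in events_a} - taken_a - pending_ids_a,
        unique_b={r.record_id for r in events_b} - taken_b - pending_ids_b,
        pending_possibles=sorted(pending, key=_pair_sort_key),
        decisions=all_decisions,
    )
    return result


# ---------------------------------------------------------------------------
# Human adjudication round-trip
# ---------------------------------------------------------------------------

REVIEW_COLUMNS = [
    "pair_id", "record_id_A", "record_id_B",
    "date_A", "date_B", "location_A", "location_B", "name_A", "name_B",
    "date_cmp", "location_cmp", "name_cmp", "decision",
]


def adjudicate_export(pending: Sequence[MatchDecision],
                      events_a: Sequence[EventRecord], events_b: Sequence[EventRecord],
                      path) -> int:
    """Write pending possible matches side-by-side for human review.

    The ``decision`` column is to be filled with ``definite`` or
    ``unique``. Returns the number of rows written.
    """
    index_a = {r.record_id: r for r in events_a}
    index_b = {r.record_id: r for r in events_b}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REVIEW_COLUMNS)
        for i, d in enumerate(pending, start=1):
            ra, rb = index_a[d.record_id_a], index_b[d.record_id_b]
            writer.writerow([
                i, ra.record_id, rb.record_id,
                ra.event_date.isoformat() if ra.event_date else "",
                rb.event_date.isoformat() if rb.event_date else "",
                ra.location_name or "", rb.location_name or "",
                ra.entity_name or "", rb.entity_name or "",
                d.agreement.date_cmp, d.agreement.location_cmp, d.agreement.name_cmp,
                "",
            ])
    return len(pending)


def adjudicate_import(path) -> dict[tuple[str, str], str]:
    """Read a filled review file back into an adjudication mapping."""
    rulings: dict[tuple[str, str], str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            decision = (row.get("decision") or "").strip().casefold()
            if decision not in ("definite", "unique"):
                raise ValueError(
                    f"pair {row.get('pair_id')}: decision must be definite or unique, got {decision!r}"
                )
            rulings[(row["record_id_A"], row["record_id_B"])] = decision
    return rulings


def apply_adjudication(result: LinkageResult, rulings: Mapping[tuple[str, str], str]) -> LinkageResult:
    """Resolve a result's pending possibles with explicit rulings."""
    known = {d.pair for d in result.pending_possibles}
    unknown = set(rulings) - known
    if unknown:
        raise ValueError(f"rulings reference unknown pairs: {sorted(unknown)[:3]}")
    taken_a = {a for a, _ in result.matched_pairs}
    taken_b = {b for _, b in result.matched_pairs}
    promoted = [d for d in result.pending_possibles if rulings.get(d.pair) == "definite"]
    matched = list(result.matched_pairs)
    matched.extend(_greedy_one_to_one(promoted, taken_a, taken_b))
    unique_a = set(result.unique_a)
    unique_b = set(result.unique_b)
    for d in result.pending_possibles:
        if d.record_id_a not in taken_a:
            unique_a.add(d.record_id_a)
        if d.record_id_b not in taken_b:
            unique_b.add(d.record_id_b)
    return LinkageResult(
        matched_pairs=sorted(matched),
        unique_a=unique_a,
        unique_b=unique_b,
        pending_possibles=[],
        decisions=dict(result.decisions),
    )


# ---------------------------------------------------------------------------
# Scoring against a truth key
# ---------------------------------------------------------------------------

def score_linkage(result: LinkageResult, truth_pairs: Iterable[tuple[str, str]]) -> dict[str, float]:
    """Pair-level precision, recall and F1 against a ground-truth key."""
    truth = set(truth_pairs)
    found = set(result.matched_pairs)
    tp = len(found & truth)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "true_pairs": len(truth), "found_pairs": len(found), "true_positives": tp}
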