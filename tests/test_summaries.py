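from datetime import date

import pytest

from carecapture import (
    attack_type_table,
    actor_and_location_breakdown,
    monthly_counts,
    union_events,
)
from carecapture.linkage import LinkageResult
from carecapture.summaries import render_report

from conftest import make_event


def empty_linkage(unique_a=(), unique_b=(), pairs=()) -> LinkageResult:
    return LinkageResult(matched_pairs=list(pairs),
                         unique_a=set(unique_a), unique_b=set(unique_b))


class TestAttackTypeTable:
    def test_single_source_event(self):
        event = make_event("A-1", attack_type="facility")
        table = attack_type_table([event], [], empty_linkage(unique_a={"A-1"}))
        row = table.loc["facility"]
        assert (row["A"], row["B"], row["total"]) == (1, 0, 1)
        assert row["A_pct"] == 100.0 and row["total_pct"] == 100.0

    def test_empty_inputs_all_zero(self):
        table = attack_type_table([], [], empty_linkage())
        assert table[["A", "B", "total", "matches"]].to_numpy().sum() == 0

    def test_pending_possibles_rejected(self):
        from carecapture.linkage import FieldAgreement, MatchDecision
        pending = [MatchDecision("A-1", "B-1",
                                 FieldAgreement("exact", "none", "none"), "possible")]
        linkage = LinkageResult(pending_possibles=pending)
        with pytest.raises(ValueError, match="pending"):
            attack_type_table([], [], linkage)

    def test_fixture_marginals(self, fixture_result):
        table = fixture_result.attack_table
        personnel = table.loc["personnel"]
        assert personnel["total"] == 143
        assert personnel["matches"] == 19
        assert personnel["A_pct"] == 54.5
        assert personnel["B_pct"] == 43.4
        assert personnel["total_pct"] == 49.8
        # conservation: totals count each record once per source
        assert table["total"].sum() == 165 + 122 == 287
        assert table["matches"].sum() == 33
        for column in ("A_pct", "B_pct", "total_pct"):
            assert table[column].sum() == pytest.approx(100.0, abs=0.2)


class TestCountryTable:
    def test_fixture_final_country_counts(self, fixture_result):
        table = fixture_result.country_table
        assert table.loc["final_included", "A"] == 23
        assert table.loc["final_included", "B"] == 26
        assert table.loc["excluded_non_whe", "A"] == 13
        assert table.loc["excluded_non_whe", "B"] == 25
        assert table.loc["countries_with_events", "A"] == 36

    def test_single_event_counts_one_country(self, registry):
        from carecapture import apply_inclusion, country_table
        event = make_event("A-1", country="Iraq")
        _, outcomes = apply_inclusion([event], registry)
        table = country_table([event], [], outcomes, registry)
        assert table.loc["final_included", "A"] == 1
        assert table.loc["final_included", "B"] == 0


class TestMonthlyCounts:
    def test_fixture_profile(self, fixture_result):
        monthly = fixture_result.monthly
        assert monthly[6] == 15 and monthly[7] == 15
        assert monthly[12] == 34
        assert monthly.sum() == 254
        assert fixture_result.unknown_dates == 0
        assert (monthly >= 15).all()

    def test_single_month_and_unknowns(self):
        events = [make_event(f"A-{i}", event_date=date(2017, 4, i + 1))
                  for i in range(3)]
        events.append(make_event("A-9", event_date=None, date_precision="unknown"))
        series, unknown = monthly_counts(events)
        assert series[4] == 3
        assert series.drop(4).sum() == 0
        assert unknown == 1

    def test_empty_union(self):
        series, unknown = monthly_counts([])
        assert series.sum() == 0 and unknown == 0

    def test_matched_pairs_counted_once(self, fixture_result):
        union = union_events(fixture_result.included_a, fixture_result.included_b,
                             fixture_result.linkage)
        assert len(union) == 254


class TestBreakdown:
    def test_fixture_ratios(self, fixture_result):
        b = fixture_result.breakdown
        assert b["unique_msf_redcross"] == {"count": 29, "base": 221, "pct": 13.1}
        assert b["matched_msf_redcross"]["count"] == 9
        assert b["matched_msf_redcross"]["pct"] == 27.3
        assert b["matched_known_actor"]["count"] == 12
        assert b["matched_known_actor"]["pct"] == 36.4
        assert b["missing_location"]["count"] == 40
        assert b["missing_location"]["pct"] == 13.9
        assert (b["missing_location"]["count_a"], b["missing_location"]["count_b"]) == (6, 34)
        assert b["rural"] == {"count": 48, "base": 287, "pct": 16.7}
        assert b["urban"]["count"] == 199
        assert b["capital_city_matches"] == {"count": 7, "base": 33, "pct": 21.2}

    def test_no_actor_flags(self):
        events = [make_event("A-1"), make_event("B-1", source="B", country="Mali")]
        b = actor_and_location_breakdown([events[0]], [events[1]],
                                         empty_linkage({"A-1"}, {"B-1"}))
        assert b["unique_msf_redcross"]["count"] == 0
        assert b["unique_msf_redcross"]["pct"] == 0.0


def test_report_rendering_is_deterministic(fixture_result):
    args = (fixture_result.attack_table, fixture_result.country_table,
            fixture_result.monthly, fixture_result.unknown_dates,
            fixture_result.breakdown)
    text = render_report(*args)
    assert text == render_report(*args)
    assert "143" in text and "12" in text
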