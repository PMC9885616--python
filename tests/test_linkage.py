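import random
from datetime import date

import pytest

from carecapture import (
    GeneratorConfig,
    LinkageConfig,
    adjudicate_export,
    adjudicate_import,
    apply_adjudication,
    apply_noise,
    classify_pair,
    compare_fields,
    generate_world,
    jaro_winkler,
    link,
    score_linkage,
    truth_key_adjudicator,
)
from carecapture.linkage import FieldAgreement

from conftest import make_event


class TestJaroWinkler:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("martha", "marhta", 0.961111),
        ("dwayne", "duane", 0.840000),
        ("dixon", "dicksonx", 0.813333),
    ])
    def test_reference_values(self, s1, s2, expected):
        assert jaro_winkler(s1, s2) == pytest.approx(expected, abs=1e-6)

    def test_bounds_and_identity(self):
        assert jaro_winkler("kabul", "kabul") == 1.0
        assert jaro_winkler("", "kabul") == 0.0
        assert 0.0 <= jaro_winkler("abc", "xyz") <= 1.0


class TestCompareFields:
    def test_same_day_is_exact(self):
        a = make_event("A-1", event_date=date(2017, 3, 10))
        b = make_event("B-1", source="B", event_date=date(2017, 3, 10))
        assert compare_fields(a, b).date_cmp == "exact"

    def test_two_day_gap_is_approximate_at_default_tolerance(self):
        a = make_event("A-1", event_date=date(2017, 3, 10))
        b = make_event("B-1", source="B", event_date=date(2017, 3, 12))
        agreement = compare_fields(a, b)
        assert agreement.date_cmp == "approximate"
        assert agreement.date_gap_days == 2
        strict = LinkageConfig(date_tolerance_days=1)
        assert compare_fields(a, b, strict).date_cmp == "none"

    def test_month_precision_rules(self):
        month_a = make_event("A-1", event_date=date(2017, 3, 1), date_precision="month")
        month_b = make_event("B-1", source="B", event_date=date(2017, 3, 1),
                             date_precision="month")
        day_b = make_event("B-2", source="B", event_date=date(2017, 3, 20))
        other_month = make_event("B-3", source="B", event_date=date(2017, 4, 1),
                                 date_precision="month")
        assert compare_fields(month_a, month_b).date_cmp == "exact"
        # month precision never grades exact against a day-precision date
        assert compare_fields(month_a, day_b).date_cmp == "approximate"
        assert compare_fields(month_a, other_month).date_cmp == "none"

    def test_absent_fields_are_unassessable(self):
        a = make_event("A-1", entity_name=None, location_name=None,
                       event_date=None, date_precision="unknown", setting="unknown")
        b = make_event("B-1", source="B", entity_name="x clinic")
        agreement = compare_fields(a, b)
        assert agreement.name_cmp == "unassessable"
        assert agreement.location_cmp == "unassessable"
        assert agreement.date_cmp == "unassessable"

    def test_similar_names_grade_approximate(self):
        a = make_event("A-1", entity_name="Al-Shifa Hospital")
        b = make_event("B-1", source="B", entity_name="Al Shifa Hospital")
        agreement = compare_fields(a, b)
        assert agreement.name_cmp == "approximate"
        assert agreement.name_score >= 0.9


class TestClassifyPair:
    @pytest.mark.parametrize("grades,status", [
        (("exact", "exact", "none"), "definite"),
        (("exact", "exact", "exact"), "definite"),
        (("exact", "approximate", "none"), "possible"),
        (("exact", "unassessable", "unassessable"), "possible"),
        (("approximate", "none", "none"), "possible"),
        (("none", "none", "none"), "unique"),
        (("unassessable", "unassessable", "unassessable"), "unique"),
    ])
    def test_rule(self, grades, status):
        agreement = FieldAgreement(*grades)
        assert classify_pair(agreement) == status

    def test_score_credits(self):
        agreement = FieldAgreement("exact", "approximate", "unassessable")
        assert agreement.score == pytest.approx(1.5)


class TestLink:
    def test_copied_dataset_matches_everything(self):
        countries = ["Iraq", "Mali", "Chad", "Sudan", "Libya"]
        events_a = [make_event(f"A-{i}", country=c, event_date=date(2017, 2, i + 1),
                               entity_name=f"unit {i}")
                    for i, c in enumerate(countries)]
        events_b = [e.copy(record_id=f"B-{i}", source="B")
                    for i, e in enumerate(events_a)]
        result = link(events_a, events_b)
        assert result.n_matched == len(countries)
        assert result.unique_a == set() and result.unique_b == set()

    def test_disjoint_countries_match_nothing(self):
        events_a = [make_event("A-1", country="Iraq")]
        events_b = [make_event("B-1", source="B", country="Mali")]
        result = link(events_a, events_b)
        assert result.matched_pairs == []
        assert result.unique_a == {"A-1"} and result.unique_b == {"B-1"}

    def test_one_to_one_under_ambiguity(self):
        # two A records both agree with one B record; only one pair may win
        a1 = make_event("A-1", entity_name="clinic one")
        a2 = make_event("A-2", entity_name="clinic one")
        b1 = make_event("B-1", source="B", entity_name="clinic one")
        result = link([a1, a2], [b1], adjudicator=lambda pending: {})
        assert result.n_matched == 1
        ids = [rid for pair in result.matched_pairs for rid in pair]
        assert len(ids) == len(set(ids))

    def test_zero_noise_world_recovers_truth_exactly(self):
        world = apply_noise(generate_world(GeneratorConfig.noiseless(
            n_true=150, seed=5)))
        result = link(world.records_a, world.records_b,
                      adjudicator=truth_key_adjudicator(world.truth_pairs))
        assert sorted(result.matched_pairs) == sorted(world.truth_pairs)
        scores = score_linkage(result, world.truth_pairs)
        assert scores["precision"] == 1.0 and scores["recall"] == 1.0

    def test_symmetry_under_list_swap(self):
        world = apply_noise(generate_world(GeneratorConfig(n_true=150, seed=9)))
        forward = link(world.records_a, world.records_b,
                       adjudicator=truth_key_adjudicator(world.truth_pairs))
        swapped_truth = [(b, a) for a, b in world.truth_pairs]
        backward = link(world.records_b, world.records_a,
                        adjudicator=truth_key_adjudicator(swapped_truth))
        assert set(forward.matched_pairs) == {(a, b) for b, a in backward.matched_pairs}

    def test_row_order_invariance(self):
        world = apply_noise(generate_world(GeneratorConfig(n_true=150, seed=13)))
        base = link(world.records_a, world.records_b,
                    adjudicator=truth_key_adjudicator(world.truth_pairs))
        rng = random.Random(99)
        shuffled_a, shuffled_b = world.records_a[:], world.records_b[:]
        rng.shuffle(shuffled_a)
        rng.shuffle(shuffled_b)
        again = link(shuffled_a, shuffled_b,
                     adjudicator=truth_key_adjudicator(world.truth_pairs))
        assert again.matched_pairs == base.matched_pairs
        assert again.unique_a == base.unique_a

    def test_unadjudicated_possibles_stay_pending_with_warning(self):
        a = make_event("A-1", entity_name=None, location_name="Karrada",
                       event_date=date(2017, 5, 2))
        b = make_event("B-1", source="B", entity_name=None, location_name="Mosul",
                       event_date=date(2017, 5, 3))
        with pytest.warns(UserWarning, match="possible"):
            result = link([a], [b])
        assert len(result.pending_possibles) == 1
        assert result.unique_a == set() and result.unique_b == set()


class TestAdjudicationRoundTrip:
    def test_fixture_review_flow(self, fixture_bundle, tmp_path, recwarn):
        from carecapture import run_pipeline

        result = run_pipeline(fixture_bundle.records_a, fixture_bundle.records_b)
        pending = result.linkage.pending_possibles
        assert len(pending) == 16

        review = tmp_path / "review.csv"
        n = adjudicate_export(pending, result.included_a, result.included_b, review)
        assert n == 16

        # fill the decision column the way the coders' consensus would
        truth = set(fixture_bundle.truth_pairs)
        text = review.read_text().splitlines()
        header = text[0].split(",")
        decision_col = header.index("decision")
        id_a, id_b = header.index("record_id_A"), header.index("record_id_B")
        filled = [text[0]]
        for line in text[1:]:
            cells = line.split(",")
            cells[decision_col] = ("definite" if (cells[id_a], cells[id_b]) in truth
                                   else "unique")
            filled.append(",".join(cells))
        review.write_text("\n".join(filled) + "\n")

        rulings = adjudicate_import(review)
        assert sum(v == "definite" for v in rulings.values()) == 4
        assert sum(v == "unique" for v in rulings.values()) == 12

        final = apply_adjudication(result.linkage, rulings)
        assert final.pending_possibles == []
        assert final.n_matched == 33
        assert set(final.matched_pairs) == truth

    def test_import_rejects_bad_decision(self, tmp_path):
        review = tmp_path / "review.csv"
        review.write_text("pair_id,record_id_A,record_id_B,decision\n1,A-1,B-1,maybe\n")
        with pytest.raises(ValueError, match="definite or unique"):
            adjudicate_import(review)

    def test_apply_rejects_unknown_pairs(self, fixture_bundle):
        from carecapture import run_pipeline

        result = run_pipeline(fixture_bundle.records_a, fixture_bundle.records_b)
        with pytest.raises(ValueError, match="unknown pairs"):
            apply_adjudication(result.linkage, {("A-none", "B-none"): "definite"})

    def test_empty_pending_writes_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        assert adjudicate_export([], [], [], path) == 0
        assert len(path.read_text().splitlines()) == 1  # header only
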