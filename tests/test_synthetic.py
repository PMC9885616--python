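import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from carecapture import (
    GeneratorConfig,
    apply_noise,
    apply_noise_and_write,
    find_duplicates,
    generate_world,
    joint_capture_probs,
    link,
    make_paper_fixture,
    read_truth_key,
    run_pipeline,
    score_linkage,
    simulate_capture_counts,
    truth_key_adjudicator,
)
from carecapture.linkage import jaro_winkler
from carecapture.event_model import normalize_compare_text
from carecapture.synthetic import TOWN_NAMES


class TestJointCaptureProbs:
    def test_independence(self):
        p11, p10, p01, p00 = joint_capture_probs(0.275, 0.205, 1.0)
        assert p11 == pytest.approx(0.275 * 0.205)
        assert p11 + p10 == pytest.approx(0.275)
        assert p11 + p01 == pytest.approx(0.205)
        assert sum((p11, p10, p01, p00)) == pytest.approx(1.0)

    @pytest.mark.parametrize("odds_ratio", [0.5, 3.0, 10.0])
    def test_margins_and_odds_ratio_preserved(self, odds_ratio):
        p1, p2 = 0.275, 0.205
        p11, p10, p01, p00 = joint_capture_probs(p1, p2, odds_ratio)
        assert p11 + p10 == pytest.approx(p1)
        assert p11 + p01 == pytest.approx(p2)
        assert (p11 * p00) / (p10 * p01) == pytest.approx(odds_ratio)

    def test_positive_dependence_inflates_overlap(self):
        indep = joint_capture_probs(0.275, 0.205, 1.0)[0]
        assert joint_capture_probs(0.275, 0.205, 3.0)[0] > indep
        assert joint_capture_probs(0.275, 0.205, 0.5)[0] < indep

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p1=0.0)
        with pytest.raises(ValueError):
            GeneratorConfig(p2=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(dependence_or=-1.0)


class TestGenerateWorld:
    def test_certain_capture_with_no_noise(self):
        config = GeneratorConfig.noiseless(n_true=50, p1=1.0, p2=1.0, seed=1)
        world = apply_noise(generate_world(config))
        assert world.n_captured_a == world.n_captured_b == 50
        assert world.n_co_captured == 50
        assert len(world.truth_pairs) == 50

    def test_overlap_within_central_99pct_binomial_band(self):
        config = GeneratorConfig(n_true=600, seed=2)
        world = generate_world(config)
        p = 0.275 * 0.205
        low = stats.binom.ppf(0.005, 600, p)
        high = stats.binom.ppf(0.995, 600, p)
        assert low <= world.n_co_captured <= high

    def test_dependence_raises_mean_overlap(self):
        draws_indep = simulate_capture_counts(200, 0.275, 0.205, 1.0,
                                              n_reps=200, seed=3)
        draws_dep = simulate_capture_counts(200, 0.275, 0.205, 3.0,
                                            n_reps=200, seed=3)
        assert draws_dep[:, 2].mean() > draws_indep[:, 2].mean()

    def test_truth_key_covers_co_captured_events(self):
        world = apply_noise(generate_world(GeneratorConfig(n_true=300, seed=4)))
        assert len(world.truth_pairs) == world.n_co_captured
        # truth pairs are one-to-one
        ids_a = [a for a, _ in world.truth_pairs]
        ids_b = [b for _, b in world.truth_pairs]
        assert len(set(ids_a)) == len(ids_a) and len(set(ids_b)) == len(ids_b)


class TestNoiseAndContamination:
    def test_zero_noise_records_equal_on_compared_fields(self):
        world = apply_noise(generate_world(GeneratorConfig.noiseless(
            n_true=100, seed=6)))
        index_b = {r.record_id: r for r in world.records_b}
        for rid_a, rid_b in world.truth_pairs:
            rec_a = next(r for r in world.records_a if r.record_id == rid_a)
            rec_b = index_b[rid_b]
            assert rec_a.event_date == rec_b.event_date
            assert rec_a.location_name == rec_b.location_name
            assert rec_a.entity_name == rec_b.entity_name

    def test_date_jitter_bounded_by_max_days(self):
        config = GeneratorConfig(n_true=120, seed=7, date_jitter_prob=1.0,
                                 date_jitter_max_days=2,
                                 location_missing_prob=0.0,
                                 location_coarsen_prob=0.0, name_perturb_prob=0.0,
                                 non_whe_rate=0.0, definition_fail_rate=0.0,
                                 aggregated_rate=0.0, duplicate_plant_count=(0, 0))
        world = apply_noise(generate_world(config))
        latent_by_id = {e.event_id: e for e in world.latent}
        for rec in world.records_a + world.records_b:
            latent = latent_by_id[world.latent_of[rec.record_id]]
            assert 1 <= abs((rec.event_date - latent.event_date).days) <= 2

    def test_planted_duplicates_found_by_dedup(self):
        config = GeneratorConfig(n_true=200, seed=8, duplicate_plant_count=(3, 0))
        world = apply_noise(generate_world(config))
        assert len(find_duplicates(world.records_a)) == 3
        assert len(find_duplicates(world.records_b)) == 0

    def test_contaminants_fail_inclusion(self):
        config = GeneratorConfig(n_true=200, seed=9)
        world = apply_noise(generate_world(config))
        result = run_pipeline(world.records_a, world.records_b,
                              adjudicator=truth_key_adjudicator(world.truth_pairs))
        funnel = result.funnel
        assert funnel["country_non_whe"].sum() > 0
        assert funnel["definition_not_met"].sum() > 0
        # contaminants never touch the linkage universe
        assert len(result.included_a) <= world.n_captured_a


class TestReproducibility:
    def test_identical_config_gives_identical_files(self, tmp_path):
        def digest(directory: Path) -> list[str]:
            return [hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(directory.iterdir())]

        config = GeneratorConfig(n_true=150, seed=10)
        apply_noise_and_write(generate_world(config), tmp_path / "one")
        apply_noise_and_write(generate_world(config), tmp_path / "two")
        assert digest(tmp_path / "one") == digest(tmp_path / "two")

    def test_truth_key_round_trip(self, tmp_path):
        world = apply_noise(generate_world(GeneratorConfig(n_true=100, seed=11)))
        paths = apply_noise_and_write(world, tmp_path)
        assert read_truth_key(paths["truth_key"]) == world.truth_pairs


class TestEndToEndRecovery:
    def test_clean_world_full_pipeline(self):
        world = apply_noise(generate_world(GeneratorConfig.noiseless(
            n_true=250, seed=12)))
        result = run_pipeline(world.records_a, world.records_b,
                              adjudicator=truth_key_adjudicator(world.truth_pairs))
        scores = score_linkage(result.linkage, world.truth_pairs)
        assert scores["precision"] == 1.0 and scores["recall"] == 1.0
        n_captured = int((world.captured_a | world.captured_b).sum())
        assert result.estimate.union_n == n_captured


class TestPaperFixture:
    def test_construction_is_deterministic(self, fixture_bundle):
        again = make_paper_fixture()
        assert again.records_a == fixture_bundle.records_a
        assert again.records_b == fixture_bundle.records_b
        assert again.truth_pairs == fixture_bundle.truth_pairs

    def test_raw_counts(self, fixture_bundle):
        assert len(fixture_bundle.records_a) == 264
        assert len(fixture_bundle.records_b) == 238
        assert len(fixture_bundle.truth_pairs) == 33

    def test_fixture_write(self, tmp_path, fixture_bundle):
        make_paper_fixture(tmp_path)
        assert (tmp_path / "events_a.csv").exists()
        pairs = read_truth_key(tmp_path / "truth_key.csv")
        assert pairs == fixture_bundle.truth_pairs


def test_town_names_are_mutually_dissimilar():
    """Distinct synthetic places must never clear the similarity threshold."""
    normalised = [normalize_compare_text(n) for n in TOWN_NAMES]
    worst = max(jaro_winkler(a, b)
                for i, a in enumerate(normalised)
                for b in normalised[i + 1:])
    assert worst < 0.9
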