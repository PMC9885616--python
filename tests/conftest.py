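from datetime import date

import pytest

from carecapture import (
    CountryRegistry,
    EventRecord,
    make_paper_fixture,
    run_pipeline,
    truth_key_adjudicator,
)


@pytest.fixture(scope="session")
def registry() -> CountryRegistry:
    return CountryRegistry.whe_2016()


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_paper_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_bundle):
    """Full replication-profile pipeline run on the constructed fixture."""
    return run_pipeline(
        fixture_bundle.records_a,
        fixture_bundle.records_b,
        profile="replication",
        adjudicator=truth_key_adjudicator(fixture_bundle.truth_pairs),
    )


def make_event(record_id="A-0001", source="A", country="Iraq",
               event_date=date(2017, 3, 10), **kwargs) -> EventRecord:
    defaults = dict(
        date_precision="day" if event_date else "unknown",
        location_name="Baghdad",
        setting="urban",
        attack_type="facility",
        named_actor="none",
        entity_name=None,
        meets_definition=True,
        is_aggregated_report=False,
    )
    defaults.update(kwargs)
    return EventRecord(record_id=record_id, source=source, country=country,
                       event_date=event_date, **defaults)
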