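"""End-to-end orchestration: ingest -> dedup -> inclusion -> linkage ->
estimation -> summaries.

Two profiles are provided. ``replication`` reproduces the published
comparison's conventions (the conservative (m-1) estimator variant and
truncation of the overlap percentage); ``default`` uses the standard
Chapman estimator and round-half-up percentages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import summaries as _summaries
from .estimation import CaptureEstimate, estimate
from .event_model import CountryRegistry, EventRecord
from .inclusion import InclusionOutcome, apply_inclusion, funnel_counts, funnel_report
from .ingest import find_duplicates, remove_duplicates, write_exclusions
from .linkage import (
    Adjudicator,
    DEFAULT_CONFIG,
    LinkageConfig,
    LinkageResult,
    adjudicate_export,
    link,
)

logger = logging.getLogger(__name__)

PROFILES = ("replication", "default")


@dataclass
class PipelineResult:
    """Everything one run produces."""

    profile: str
    linkage_config: LinkageConfig
    outcomes: list[InclusionOutcome]
    funnel: pd.DataFrame
    included_a: list[EventRecord]
    included_b: list[EventRecord]
    duplicate_ids: set[str]
    linkage: LinkageResult
    estimate: Optional[CaptureEstimate] = None
    attack_table: Optional[pd.DataFrame] = None
    country_table: Optional[pd.DataFrame] = None
    monthly: Optional[pd.Series] = None
    unknown_dates: int = 0
    breakdown: Optional[dict] = None

    @property
    def finalised(self) -> bool:
        return not self.linkage.pending_possibles


def run_pipeline(records_a: Sequence[EventRecord], records_b: Sequence[EventRecord],
                 *, profile: str = "default",
                 linkage_config: LinkageConfig = DEFAULT_CONFIG,
                 registry: Optional[CountryRegistry] = None,
                 adjudicator: Optional[Adjudicator] = None) -> PipelineResult:
    """Run the full two-source comparison.

    When possible matches remain unadjudicated the result carries them in
    ``linkage.pending_possibles`` and the downstream tables are left unset
    (export the pending pairs for review, then re-run with rulings).
    """
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}, got {profile!r}")
    registry = registry or CountryRegistry.whe_2016()

    dup_ids: set[str] = set()
    kept: dict[str, list[EventRecord]] = {}
    for source, records in (("A", records_a), ("B", records_b)):
        groups = find_duplicates(records, linkage_config)
        kept[source], dropped = remove_duplicates(records, groups)
        dup_ids |= dropped
        logger.info("source %s: %d duplicate group(s), %d record(s) dropped",
                    source, len(groups), len(dropped))

    included_a, outcomes_a = apply_inclusion(list(records_a), registry, dup_ids)
    included_b, outcomes_b = apply_inclusion(list(records_b), registry, dup_ids)
    outcomes = outcomes_a + outcomes_b
    funnel = funnel_counts(outcomes)

    linkage = link(included_a, included_b, linkage_config, adjudicator)

    result = PipelineResult(
        profile=profile,
        linkage_config=linkage_config,
        outcomes=outcomes,
        funnel=funnel,
        included_a=included_a,
        included_b=included_b,
        duplicate_ids=dup_ids,
        linkage=linkage,
    )
    if not result.finalised:
        logger.warning("%d possible matches pending adjudication; "
                       "summaries and estimates deferred",
                       len(linkage.pending_possibles))
        return result

    r1, r2, m = len(included_a), len(included_b), linkage.n_matched
    variant = "paper" if profile == "replication" else "standard"
    if variant == "paper" and m < 2:
        logger.warning("overlap m=%d too small for the (m-1) variant; "
                       "falling back to standard Chapman", m)
        variant = "standard"
    if r1 + r2 - m > 0 and m >= 1:
        result.estimate = estimate(r1, r2, m, variant=variant,
                                   truncate_overlap=(profile == "replication"))
    result.attack_table = _summaries.attack_type_table(included_a, included_b, linkage)
    result.country_table = _summaries.country_table(list(records_a), list(records_b),
                                                    outcomes, registry)
    union = _summaries.union_events(included_a, included_b, linkage)
    result.monthly, result.unknown_dates = _summaries.monthly_counts(union)
    result.breakdown = _summaries.actor_and_location_breakdown(
        included_a, included_b, linkage)
    return result


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write the run's artifacts; deterministic content (no timestamps)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["funnel_csv"] = out / "funnel.csv"
    result.funnel.to_csv(paths["funnel_csv"])
    paths["funnel_txt"] = out / "funnel.txt"
    paths["funnel_txt"].write_text(funnel_report(result.outcomes) + "\n", encoding="utf-8")

    paths["exclusions"] = out / "exclusions.csv"
    write_exclusions(
        ((o.record_id, o.reason) for o in result.outcomes if not o.included),
        paths["exclusions"],
    )

    paths["matched_pairs"] = out / "matched_pairs.csv"
    with paths["matched_pairs"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("record_id_A,record_id_B\n")
        for rid_a, rid_b in result.linkage.matched_pairs:
            fh.write(f"{rid_a},{rid_b}\n")

    if result.linkage.pending_possibles:
        paths["review"] = out / "review.csv"
        adjudicate_export(result.linkage.pending_possibles,
                          result.included_a, result.included_b, paths["review"])
        return paths

    if result.estimate is not None:
        paths["estimates"] = out / "estimates.json"
        with paths["estimates"].open("w", encoding="utf-8") as fh:
            json.dump(result.estimate.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    paths["attack_table"] = out / "attack_type_table.csv"
    result.attack_table.to_csv(paths["attack_table"])
    paths["country_table"] = out / "country_table.csv"
    result.country_table.to_csv(paths["country_table"])
    paths["monthly"] = out / "monthly_counts.csv"
    result.monthly.to_csv(paths["monthly"])
    paths["breakdown"] = out / "breakdown.json"
    with paths["breakdown"].open("w", encoding="utf-8") as fh:
        json.dump(result.breakdown, fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["report"] = out / "report.txt"
    paths["report"].write_text(
        _summaries.render_report(result.attack_table, result.country_table,
                                 result.monthly, result.unknown_dates,
                                 result.breakdown) + "\n",
        encoding="utf-8",
    )

    manifest = {
        "profile": result.profile,
        "linkage_config": dataclasses.asdict(result.linkage_config),
        "n_included_a": len(result.included_a),
        "n_included_b": len(result.included_b),
        "n_matched": result.linkage.n_matched,
        "n_duplicates_removed": len(result.duplicate_ids),
    }
    paths["run_manifest"] = out / "run_manifest.json"
    with paths["run_manifest"].open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
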