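# Methods

This note documents the statistical model, the matching procedure, the
synthetic data generator and the numerical conventions used in
`carecapture`, including the design choices made where more than one
reasonable convention exists.

## Two-list capture–recapture model

The target quantity is the number `N` of publicly-reportable attack events
in a fixed year and country scope. Two organisations compile lists of such
events independently; list 1 contains `r1` in-scope events, list 2 contains
`r2`, and record linkage identifies `m` events present on both. Under the
classical two-list model — every event has the same probability of entering
each list, and the lists are independent — the bias-corrected (Chapman)
estimator is

    N̂ = (r1 + 1)(r2 + 1) / (m + 1) − 1,

with variance

    Var(N̂) = (r1 + 1)(r2 + 1)(r1 − m)(r2 − m) / ((m + 1)² (m + 2)),

and a normal-approximation confidence interval (default level 0.95),
clipped below at the observed union `r1 + r2 − m`, since the universe
cannot be smaller than what was observed. The package additionally
implements a conservative variant that divides by `(m − 1)` instead of
`(m + 1)`; it exceeds the standard form whenever `m ≥ 2` and is undefined
for `m ≤ 1`. The **replication profile** uses this variant because the
published headline figure (637 events from `r1 = 165`, `r2 = 122`,
`m = 33`) is only consistent with division by `m − 1`; the standard form
gives ≈ 599.5 for the same counts. The **default profile** uses standard
Chapman. Reported point estimates are floored to integers when labelled as
event counts.

Coverage is reported three ways — `r1/N̂`, `r2/N̂` and `(r1 + r2)/N̂` —
because published discussion of "what fraction each dataset captures" is
ambiguous between these bases (for the replication counts they are ≈ 26%,
≈ 19% and ≈ 45%). The package asserts none of them as *the* coverage; all
three appear in the estimate block.

Model assumptions worth stating plainly: closed universe (one year, fixed
country list), homogeneous capture within each list, and list
independence. Real media-derived lists violate independence (a
high-profile attack is likelier to enter both lists), which biases `m`
upward and `N̂` downward. The generator's odds-ratio knob (below) exists to
quantify that bias rather than pretend it away.

## Inclusion filtering

Scope is the 47 WHO Health Emergencies (WHE) countries/territories of the
2016 list — 5 grade-3, 12 grade-2 and 14 grade-1 emergencies plus 16
protracted emergencies — with the Syrian Arab Republic listed but excluded
from analysis (reporting volume and missing detail there make duplicate
elimination unreliable). Canonical country names are the registry
spellings; a small alias table maps common variants ("DRC", "CAR",
"Syria", …). A country name outside the registry is kept verbatim and
classifies as non-WHE; only a missing name is an error.

Each record carries coder flags consumed as-is: `meets_definition` (the
WHO attack definition — any act of verbal or physical violence,
obstruction or threat that interferes with the availability, access or
delivery of health services) and `is_aggregated_report` (summary reports
covering several attacks, which are not analysable events). The package
deliberately does **not** infer these from description text; definition
coding was a human judgement and text classification is out of scope.

Checks run in a fixed order — duplicate, country scope, definition,
aggregated report — and the first failure is the recorded reason, so the
funnel's reason counts are unambiguous and sum to the raw record count per
source. The order itself is a convention (sources publishing such
comparisons report only combined counts); fixing it is what makes the
funnel machine-readable.

## Record linkage

Candidate pairs are generated only within identical-country blocks —
matching across countries is never attempted. For each pair, three fields
are graded `exact` / `approximate` / `none` / `unassessable`:

* **date** — exact: same calendar day (both day-precision); approximate:
  gap ≤ `date_tolerance_days` (default 2). Month-precision dates are exact
  only against month-precision dates of the same month, approximate
  against a day-precision date in that month — a month-level report should
  never by itself create a definite match against a day-level one.
* **location**, **name** — compared on case-folded, diacritic-stripped,
  whitespace-collapsed text; exact: equal; approximate: Jaro–Winkler
  similarity ≥ 0.90 (both thresholds configurable). Jaro–Winkler is
  implemented in-package and validated against published reference values.
* A field absent on either side is `unassessable` and never counts toward
  agreement.

Classification: **definite** requires ≥ 2 exact fields; anything weaker
but non-empty (≥ 1 approximate, or exactly one exact) is **possible**;
otherwise **unique**. The underlying published rule ("two or more
matched") does not separate definite from possible matches crisply — the
original coders resolved the grey zone by consensus. The package mirrors
that: automation is conservative (definite only on strong agreement), and
everything in the grey zone goes to an adjudicator — the ground-truth key
in synthetic mode, an exported review CSV (filled with
`definite`/`unique` decisions and re-imported) in real mode.

Definite pairs are resolved to a one-to-one matching greedily: score
descending (exact = 1, approximate = 0.5 per field), then date gap
ascending, then lexicographic id pair. The tie-break makes the matching
invariant to input row order and to swapping the two lists. Within-source
duplicate detection reuses the same definite rule between same-source
records (duplicates arise from two differing reports of one event, so
byte-equality would be too strict); groups are connected components, and
the lexicographically smallest record id in each group is kept — an
arbitrary but deterministic and logged policy.

Threshold defaults (tolerance 2 days, similarity 0.90) were calibrated
once against the generator's mild-noise profile and then frozen; the
calibration target was pair-level F1 ≥ 0.95 on 600-event worlds, which the
acceptance suite re-checks.

## Synthetic worlds

`generate_world` draws `n_true` latent events (default 600) with country
from a Zipf-weighted mix over the 31 in-scope countries that carry events
in the emulated year, date uniform over the year, a unique
district/site location, a unique facility name, attack type from the
emulated marginal mix, and actor/setting flags. Capture indicators come
from a 2×2 joint distribution with margins `p1 = 0.275`, `p2 = 0.205`
(expected list sizes ≈ 165 and ≈ 123, expected overlap ≈ 34) and an
odds-ratio tilt for dependence; the tilt solves the quadratic for `p11`
at fixed margins, so `odds_ratio = 1` is exact independence.

Observed records then receive reporting noise, each independently per
record: date jitter ±1 day with probability 0.3, location dropped with
probability 0.14 (setting becomes unknown, mimicking how location-less
reports also lack an urban/rural coding), otherwise coarsened to the
district with probability 0.2, and facility-name perturbation (single
character edits, occasionally a dropped token) with probability 0.2.
Contaminants are appended per source — non-WHE-country events (rate 0.30
per captured record), definition-failing events such as protests (0.10),
aggregated reports (0.02) — plus planted duplicates (2 in source A, 1 in
B), so the inclusion and dedup stages have real work to do. Rates mirror
the emulated data-preparation funnel. Identical config and seed give
byte-identical output files.

What the generator does *not* emulate: free-text descriptions, geocoding,
multi-lingual names, heterogeneous per-event capture probabilities, and
temporal clustering of attacks. Passing tests therefore demonstrate the
pipeline's correctness and the estimators' behaviour under the stated
model, not performance on raw field data, whose noise is uglier.

`make_paper_fixture` is different in kind: a *constructed*, fully
deterministic pair of datasets (264/238 raw records) whose pipeline run
lands exactly on the emulated comparison — included 165/122, 33 matched
pairs (29 auto-definite plus 4 adjudicated from 16 possibles), union 254,
overlap 12.9%, the attack-type marginals, monthly lows of 15 in June/July
and a high of 34 in December, and the actor/location shares (29/221 =
13.1%, 40/287 = 13.9%, 7/33 = 21.2%, 48/287 = 16.7%). It is an emulation
surface for regression tests — the real records are not redistributable —
and every count above is produced by running the pipeline, not asserted.
Where the published intermediate country rows are internally inconsistent,
the fixture reproduces the final-countries row (23 and 26) and the
event-level funnel, and lets the middle rows fall out of the data.

## Descriptive summaries

The comparison tables intentionally use different denominators, and each
output states its base: attack-type totals count each record once per
source (so 165 + 122 = 287 with matches shown in parentheses), monthly
counts and the overlap use the union (254), the named-actor share uses
unique events only (221), and matched-pair shares use 33. Percentages are
rounded half-up to one decimal, except the replication profile's overlap
percentage, which truncates (100·33/254 = 12.99… prints as 12.9 only under
truncation); the estimate block records which rule produced it. For a
matched pair whose sources disagree on attack type, the pair is tabulated
under the first list's type and the conflict is logged. "Capital-city"
matched pairs are identified against a built-in capital registry for the
WHE countries, since records carry no city-size field.

## Numerical and degenerate-input conventions

* Overlap percentage is undefined for an empty union (error), and the
  conservative estimator for `m ≤ 1` (error; the pipeline falls back to
  standard Chapman with a warning).
* Month-precision dates are stored as the first of the month with a
  precision flag; unparseable dates keep the record with unknown precision
  and a logged warning.
* Empty inputs run cleanly end to end and produce all-zero tables.
* The synthetic simulation sizes used in the test and acceptance suites
  (600-event worlds, 500 capture-only replicates, three mild-noise linkage
  worlds) were chosen as the smallest sizes at which the Monte-Carlo
  noise is comfortably below the asserted tolerances.

## Known limitations

* Two lists only; log-linear multi-list models and Bayesian population
  estimates are out of scope.
* Linkage is rule-based; no probabilistic (Fellegi–Sunter) weights.
* Country blocking means an event recorded under different countries by
  the two sources can never match.
* The capture model's independence and homogeneity assumptions are known
  to fail for media data; the dependence knob quantifies but does not
  correct the resulting bias.
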