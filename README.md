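# carecapture

Two-list record linkage and capture–recapture estimation for
publicly-reported attacks on health care.

## The problem

Attacks on health facilities, transport, personnel and patients are
documented by several organisations that independently compile event lists
from public sources (media monitoring, alerts, curated newsletters). Two
such lists for the same year and the same countries typically agree on far
fewer events than either contains — and that disagreement is informative:
treated as two independent "captures" of the same latent universe of
events, the overlap lets one estimate how many publicly-reportable attacks
happened in total, and hence how severe underreporting is.

`carecapture` implements that comparison as a reusable pipeline for
epidemiologists and humanitarian-data analysts:

1. **Ingest & dedup** — read each source's event CSV, detect within-source
   duplicate reports of one event.
2. **Inclusion filtering** — restrict both lists to a common attack
   definition and geographic scope (the 47 WHO Health Emergencies
   countries, Syria excluded), with machine-readable reason codes for every
   excluded record.
3. **Record linkage** — classify cross-source pairs within country blocks
   as *definite match* (≥ 2 of date / location / facility-or-victim name
   agree exactly), *possible match* (weaker agreement, resolved by an
   adjudicator), or *unique*, and resolve a deterministic one-to-one
   matching.
4. **Estimation** — from list sizes `r1`, `r2` and overlap `m`, compute the
   union `r1 + r2 − m`, the overlap percentage, and the total-universe
   estimates (see below) with variance and confidence interval.
5. **Summaries** — attack-type, country, monthly, actor and location
   comparison tables with explicit denominators.

A synthetic two-source world generator (latent events, per-source capture
probabilities, an odds-ratio tilt for list dependence, reporting noise,
contaminant events, a ground-truth match key) makes every stage testable
without access to the original confidential datasets.

## The estimator

With `r1` and `r2` events on the two lists and `m` on both, the
bias-corrected two-list (Chapman) estimator of the universe size is

```
N̂ = (r1 + 1)(r2 + 1) / (m + 1) − 1
```

with variance `(r1+1)(r2+1)(r1−m)(r2−m) / ((m+1)²(m+2))`. The package also
implements a more conservative variant that divides by `(m − 1)` — always
larger for `m ≥ 2` — which the replication profile uses to reproduce the
published headline figure. Both assume independent lists with homogeneous
capture probabilities; the synthetic generator's dependence knob exists
precisely to measure the bias when that fails.

## Worked example

Emit the deterministic replication fixture (two event CSVs plus a
ground-truth match key) and run the pipeline on it:

```
$ carecapture fixture --out fx
wrote fixture: 264/238 records, 33 truth pairs

$ carecapture run --events-a fx/events_a.csv --events-b fx/events_b.csv \
      --truth-key fx/truth_key.csv --profile replication --out run
included 165/122, matched 33; outputs in run
union 254, overlap 12.9%, standard Chapman 599.5, conservative variant 637.1
```

Reading the numbers: from 264 and 238 raw records, inclusion filtering and
dedup leave 165 and 122 analysable events; linkage finds 33 events present
on both lists, so the observed universe is 254 distinct events of which
only 12.9% were caught by both sources. The conservative two-list estimate
of the full publicly-reportable universe is ⌊637.1⌋ = 637 events — each
list alone saw roughly a quarter of it. The run directory contains the
funnel, the matched pairs, the estimate block and the comparison report,
e.g.:

```
Affecting medical personnel: A 90 (54.5%), B 53 (43.4%), total 143 (19) (49.8%)
...
unique_msf_redcross: 29/221 = 13.1%
missing_location: 40/287 = 13.9%
capital_city_matches: 7/33 = 21.2%
```

Without `--truth-key` the possible matches are exported to `review.csv`
for human adjudication; fill the `decision` column and finish with
`carecapture adjudicate`. Synthetic worlds for method evaluation come from
`carecapture simulate --seed 3 --n-true 600 --out world`.

The same flows are available as library calls (`make_paper_fixture`,
`generate_world`, `run_pipeline`, `chapman`, …); see the module docstrings
and `docs/methods.md`.

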