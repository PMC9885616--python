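"""Synthetic two-source event worlds with ground truth.

Two generators live here:

* :func:`generate_world` / :func:`apply_noise` — a stochastic latent
  universe of attack events, each captured by source A and/or source B
  with configurable marginal probabilities and an odds-ratio tilt for
  capture dependence (1 = independent lists). Observed records get
  reporting noise (date jitter, location coarsening or loss, name typos)
  plus out-of-scope contaminants (non-WHE countries, definition-failing
  events such as protests, aggregated reports) and planted within-source
  duplicates. The truth key maps observed records back to latent events,
  so linkage and the capture-recapture estimators can be scored exactly.

* :func:`make_paper_fixture` — a *constructed* (not sampled) pair of
  datasets whose pipeline outputs land exactly on a published two-source
  comparison: raw sizes 264/238, definition exclusions 16/34, included
  165/122, 33 matched pairs, union 254, the attack-type marginals, the
  monthly profile (lows of 15 in June and July, high of 34 in December)
  and the actor/location shares. It is an emulation surface for
  regression tests, not a re-sampling of the real data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .event_model import ATTACK_TYPES, CAPITALS, EventRecord
from .ingest import write_events

# ---------------------------------------------------------------------------
# Shared vocabulary for generated worlds
# ---------------------------------------------------------------------------

#: The 31 in-scope countries that end up with analysable events in the
#: emulated study year; the stochastic generator samples from these too.
STUDY_COUNTRIES = (
    # countries where the fixture places matched pairs
    "Afghanistan", "Central African Republic", "Democratic Republic of the Congo",
    "Iraq", "Libya", "Nigeria", "Pakistan", "South Sudan", "Sudan",
    # further countries captured by both sources
    "Yemen", "Cameroon", "Ethiopia", "Niger", "Ukraine", "Mali",
    "Somalia", "Turkey", "Colombia",
    # captured by source A only
    "Bangladesh", "Nepal", "Thailand", "Egypt", "Jordan",
    # captured by source B only
    "Papua New Guinea", "The Philippines", "West Bank and Gaza Strip",
    "Burkina Faso", "Chad", "Lebanon", "The Gambia", "Zimbabwe",
)

#: Out-of-scope (non-WHE) countries used for contaminant events.
NON_WHE_COUNTRIES = (
    "France", "Germany", "India", "Brazil", "Mexico", "United States",
    "Russian Federation", "China", "Australia", "Japan", "Spain", "Italy",
    "Greece", "Canada", "Argentina", "Chile", "Peru", "Norway", "Sweden",
    "Finland", "Poland", "Portugal", "Ireland", "Austria", "Belgium",
)

#: Synthetic town names chosen to be mutually dissimilar (low pairwise
#: Jaro-Winkler), so distinct places never grade as approximate matches.
TOWN_NAMES = (
    "Altunkara", "Birstovo", "Cenlabad", "Dhurkot", "Eskaleni", "Firozwal",
    "Gomanti", "Hastiria", "Ivandale", "Jokulpur", "Kermasan", "Lubovets",
    "Mirzapol", "Nantouri", "Ossorova", "Pilkheti", "Qaransor", "Rudkoba",
    "Sentavio", "Tirgoman", "Ulbarin", "Vostapur", "Wandikor", "Xalimani",
    "Yerbostan", "Zukotira", "Ablenka", "Brivamo", "Cordutan", "Drosnima",
    "Elvantor", "Fuktaria", "Grelodze", "Hunamkot", "Ispolena", "Jarkuta",
    "Kvemorin", "Lontarsi", "Morvelak", "Nubraket",
)

#: Attack-type mix of the emulated comparison (total-column proportions).
DEFAULT_ATTACK_WEIGHTS = {
    "access_delivery": 0.108,
    "ambulance": 0.101,
    "facility": 0.251,
    "personnel": 0.498,
    "patient": 0.042,
}


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a stochastic two-list world.

    The defaults emulate the comparison year: ~600 latent events over a
    skewed country mix, captured with marginal probabilities 0.275 and
    0.205 (expected list sizes ~165 and ~123, expected overlap ~34 under
    independence), mild reporting noise, and contamination/duplicate rates
    in line with the observed data-preparation funnel.
    """

    n_true: int = 600
    p1: float = 0.275
    p2: float = 0.205
    dependence_or: float = 1.0
    country_weights: Optional[dict[str, float]] = None
    attack_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTACK_WEIGHTS))
    non_whe_rate: float = 0.30
    definition_fail_rate: float = 0.10
    aggregated_rate: float = 0.02
    date_jitter_prob: float = 0.3
    date_jitter_max_days: int = 1
    location_missing_prob: float = 0.14
    location_coarsen_prob: float = 0.2
    name_perturb_prob: float = 0.2
    duplicate_plant_count: tuple[int, int] = (2, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true <= 0:
            raise ValueError("n_true must be positive")
        for name in ("p1", "p2"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {p}")
        if self.dependence_or <= 0:
            raise ValueError("dependence_or must be positive")
        for name in ("non_whe_rate", "definition_fail_rate", "aggregated_rate",
                     "date_jitter_prob", "location_missing_prob",
                     "location_coarsen_prob", "name_perturb_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def noiseless(cls, **overrides) -> "GeneratorConfig":
        """A clean world: no reporting noise, contaminants or duplicates."""
        clean = dict(
            non_whe_rate=0.0, definition_fail_rate=0.0, aggregated_rate=0.0,
            date_jitter_prob=0.0, location_missing_prob=0.0,
            location_coarsen_prob=0.0, name_perturb_prob=0.0,
            duplicate_plant_count=(0, 0),
        )
        clean.update(overrides)
        return cls(**clean)


def joint_capture_probs(p1: float, p2: float, odds_ratio: float) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of the 2x2 capture table
    with the given margins and odds ratio.

    The odds ratio tilts the joint distribution at fixed margins;
    ``odds_ratio=1`` gives independence (p11 = p1*p2), >1 positive list
    dependence (overlap inflated), <1 negative dependence.
    """
    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p1 * p2
    else:
        # (psi-1) p11^2 - [1 + (psi-1)(p1+p2)] p11 + psi p1 p2 = 0
        psi = odds_ratio
        a = psi - 1.0
        s = 1.0 + a * (p1 + p2)
        disc = s * s - 4.0 * a * psi * p1 * p2
        p11 = (s - math.sqrt(disc)) / (2.0 * a)
    p10, p01 = p1 - p11, p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    cells = (p11, p10, p01, p00)
    if any(c < -1e-12 for c in cells):
        raise ValueError(
            f"odds ratio {odds_ratio} infeasible for margins p1={p1}, p2={p2}")
    return tuple(max(c, 0.0) for c in cells)


# ---------------------------------------------------------------------------
# Latent world
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentEvent:
    event_id: int
    country: str
    event_date: date
    location: str
    entity_name: str
    attack_type: str
    named_actor: str
    setting: str


@dataclass
class SyntheticWorld:
    """Latent events, capture indicators, observed records and truth key."""

    config: GeneratorConfig
    latent: list[LatentEvent]
    captured_a: np.ndarray
    captured_b: np.ndarray
    records_a: list[EventRecord] = field(default_factory=list)
    records_b: list[EventRecord] = field(default_factory=list)
    truth_pairs: list[tuple[str, str]] = field(default_factory=list)
    latent_of: dict[str, int] = field(default_factory=dict)
    noise_log: list[str] = field(default_factory=list)

    @property
    def n_captured_a(self) -> int:
        return int(self.captured_a.sum())

    @property
    def n_captured_b(self) -> int:
        return int(self.captured_b.sum())

    @property
    def n_co_captured(self) -> int:
        return int((self.captured_a & self.captured_b).sum())


def _default_country_weights() -> dict[str, float]:
    # Zipf-like skew: a few crisis countries dominate reporting.
    raw = {c: 1.0 / (rank + 1) for rank, c in enumerate(STUDY_COUNTRIES)}
    total = sum(raw.values())
    return {c: w / total for c, w in raw.items()}


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Draw the latent event universe and per-source capture indicators."""
    rng = np.random.default_rng(config.seed)
    weights = config.country_weights or _default_country_weights()
    countries = list(weights)
    probs = np.array([weights[c] for c in countries], dtype=float)
    probs = probs / probs.sum()

    attack_types = list(config.attack_type_weights)
    attack_probs = np.array([config.attack_type_weights[t] for t in attack_types])
    attack_probs = attack_probs / attack_probs.sum()
    unknown = set(attack_types) - set(ATTACK_TYPES)
    if unknown:
        raise ValueError(f"unknown attack types in weights: {sorted(unknown)}")

    start = date(2017, 1, 1)
    latent: list[LatentEvent] = []
    for i in range(config.n_true):
        country = countries[rng.choice(len(countries), p=probs)]
        event_date = start + timedelta(days=int(rng.integers(0, 365)))
        district = int(rng.integers(1, 13))
        latent.append(LatentEvent(
            event_id=i,
            country=country,
            event_date=event_date,
            location=f"District {district} site {i:04d}",
            entity_name=f"{TOWN_NAMES[i % len(TOWN_NAMES)]} clinic {i:04d}",
            attack_type=attack_types[rng.choice(len(attack_types), p=attack_probs)],
            named_actor=("msf_redcross" if rng.random() < 0.13
                         else "other" if rng.random() < 0.11 else "none"),
            setting="urban" if rng.random() < 0.8 else "rural",
        ))

    p11, p10, p01, p00 = joint_capture_probs(config.p1, config.p2, config.dependence_or)
    u = rng.random(config.n_true)
    cap_a = u < (p11 + p10)
    cap_b = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))
    return SyntheticWorld(config=config, latent=latent,
                          captured_a=cap_a, captured_b=cap_b)


# ---------------------------------------------------------------------------
# Observation: noise, contamination, duplicates
# ---------------------------------------------------------------------------

def _perturb_name(name: str, rng: np.random.Generator) -> str:
    if rng.random() < 0.2 and " " in name:
        return name.rsplit(" ", 1)[0]          # drop the last token
    pos = int(rng.integers(0, len(name)))
    if rng.random() < 0.5:
        return name[:pos] + name[pos + 1:]      # delete one character
    repl = chr(ord("a") + int(rng.integers(0, 26)))
    return name[:pos] + repl + name[pos + 1:]   # substitute one character


def _observe(latent: LatentEvent, source: str, record_id: str,
             config: GeneratorConfig, rng: np.random.Generator,
             log: list[str]) -> EventRecord:
    event_date = latent.event_date
    if config.date_jitter_prob and rng.random() < config.date_jitter_prob:
        shift = int(rng.integers(1, config.date_jitter_max_days + 1))
        if rng.random() < 0.5:
            shift = -shift
        event_date = event_date + timedelta(days=shift)
        log.append(f"{record_id}: date jittered {shift:+d}d")

    location: Optional[str] = latent.location
    setting = latent.setting
    if config.location_missing_prob and rng.random() < config.location_missing_prob:
        location, setting = None, "unknown"
        log.append(f"{record_id}: location dropped")
    elif config.location_coarsen_prob and rng.random() < config.location_coarsen_prob:
        location = latent.location.split(" site ")[0]
        log.append(f"{record_id}: location coarsened to {location!r}")

    entity: Optional[str] = latent.entity_name
    if config.name_perturb_prob and rng.random() < config.name_perturb_prob:
        entity = _perturb_name(entity, rng)
        log.append(f"{record_id}: name perturbed to {entity!r}")

    return EventRecord(
        record_id=record_id, source=source, country=latent.country,
        event_date=event_date, date_precision="day",
        location_name=location, setting=setting,
        attack_type=latent.attack_type, named_actor=latent.named_actor,
        entity_name=entity, meets_definition=True, is_aggregated_report=False,
        description=f"synthetic report of latent event {latent.event_id}",
    )


def _contaminants(source: str, start_serial: int, n_records: int,
                  config: GeneratorConfig, rng: np.random.Generator) -> list[EventRecord]:
    out: list[EventRecord] = []
    serial = start_serial
    start = date(2017, 1, 1)

    def base(country: str, **kw) -> EventRecord:
        nonlocal serial
        serial += 1
        return EventRecord(
            record_id=f"{source}-{serial:04d}", source=source, country=country,
            event_date=start + timedelta(days=int(rng.integers(0, 365))),
            date_precision="day",
            location_name=f"{TOWN_NAMES[int(rng.integers(0, len(TOWN_NAMES)))]} outskirts",
            setting="urban", attack_type="personnel", named_actor="none",
            description="synthetic contaminant", **kw,
        )

    for _ in range(int(rng.binomial(n_records, config.non_whe_rate))):
        country = NON_WHE_COUNTRIES[int(rng.integers(0, len(NON_WHE_COUNTRIES)))]
        out.append(base(country, meets_definition=True))
    for _ in range(int(rng.binomial(n_records, config.definition_fail_rate))):
        country = STUDY_COUNTRIES[int(rng.integers(0, len(STUDY_COUNTRIES)))]
        out.append(base(country, meets_definition=False))
    for _ in range(int(rng.binomial(n_records, config.aggregated_rate))):
        country = STUDY_COUNTRIES[int(rng.integers(0, len(STUDY_COUNTRIES)))]
        out.append(base(country, is_aggregated_report=True))
    return out


def apply_noise(world: SyntheticWorld) -> SyntheticWorld:
    """Realise observed records from the latent world (idempotent)."""
    if world.records_a or world.records_b:
        return world
    config = world.config
    rng = np.random.default_rng(config.seed + 1)
    log = world.noise_log

    serial_a = serial_b = 0
    for latent, in_a, in_b in zip(world.latent, world.captured_a, world.captured_b):
        rid_a = rid_b = None
        if in_a:
            serial_a += 1
            rid_a = f"A-{serial_a:04d}"
            world.records_a.append(_observe(latent, "A", rid_a, config, rng, log))
            world.latent_of[rid_a] = latent.event_id
        if in_b:
            serial_b += 1
            rid_b = f"B-{serial_b:04d}"
            world.records_b.append(_observe(latent, "B", rid_b, config, rng, log))
            world.latent_of[rid_b] = latent.event_id
        if rid_a and rid_b:
            world.truth_pairs.append((rid_a, rid_b))

    world.records_a.extend(_contaminants("A", 8000, serial_a, config, rng))
    world.records_b.extend(_contaminants("B", 8000, serial_b, config, rng))

    for source, records, count in (("A", world.records_a, config.duplicate_plant_count[0]),
                                   ("B", world.records_b, config.duplicate_plant_count[1])):
        candidates = [r for r in records if r.meets_definition and
                      r.country in STUDY_COUNTRIES][:count]
        for i, original in enumerate(candidates, start=1):
            copy = original.copy(record_id=f"{source}-9{i:03d}",
                                 description="synthetic duplicate report")
            records.append(copy)
            log.append(f"{copy.record_id}: planted duplicate of {original.record_id}")
    return world


def apply_noise_and_write(world: SyntheticWorld, out_dir) -> dict[str, Path]:
    """Realise the observed datasets and write them with their truth key.

    Emits ``events_a.csv``, ``events_b.csv``, ``truth_key.csv`` and
    ``manifest.json`` (config echo, seed, counts) into ``out_dir``.
    """
    apply_noise(world)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events_a": out_dir / "events_a.csv",
        "events_b": out_dir / "events_b.csv",
        "truth_key": out_dir / "truth_key.csv",
        "manifest": out_dir / "manifest.json",
    }
    write_events(world.records_a, paths["events_a"])
    write_events(world.records_b, paths["events_b"])
    with paths["truth_key"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("record_id_A,record_id_B,latent_event_id\n")
        for rid_a, rid_b in world.truth_pairs:
            fh.write(f"{rid_a},{rid_b},{world.latent_of[rid_a]}\n")
    config_dict = dataclasses.asdict(world.config)
    config_dict["duplicate_plant_count"] = list(config_dict["duplicate_plant_count"])
    manifest = {
        "config": config_dict,
        "seed": world.config.seed,
        "n_true": world.config.n_true,
        "n_records_a": len(world.records_a),
        "n_records_b": len(world.records_b),
        "n_captured_a": world.n_captured_a,
        "n_captured_b": world.n_captured_b,
        "n_co_captured": world.n_co_captured,
    }
    with paths["manifest"].open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def simulate_capture_counts(n_true: int, p1: float, p2: float,
                            odds_ratio: float = 1.0, n_reps: int = 500,
                            seed: int = 0) -> np.ndarray:
    """Replicate list sizes (r1, r2, m) under the capture model only.

    Skips event attributes and reporting noise — this is the sampling
    distribution the capture-recapture estimators see when linkage is
    perfect. Returns an (n_reps, 3) integer array.
    """
    rng = np.random.default_rng(seed)
    p11, p10, p01, _ = joint_capture_probs(p1, p2, odds_ratio)
    u = rng.random((n_reps, n_true))
    cap_a = u < (p11 + p10)
    cap_b = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))
    return np.stack([cap_a.sum(axis=1), cap_b.sum(axis=1),
                     (cap_a & cap_b).sum(axis=1)], axis=1)


def read_truth_key(path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            rid_a, rid_b, _ = line.rstrip("\n").split(",")
            pairs.append((rid_a, rid_b))
    return pairs


# ---------------------------------------------------------------------------
# Constructed replication fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    records_a: list[EventRecord]
    records_b: list[EventRecord]
    truth_pairs: list[tuple[str, str]]


# matched pairs per country (33 in total across nine countries)
_MATCH_COUNTRIES = [
    ("Afghanistan", 5), ("Central African Republic", 2),
    ("Democratic Republic of the Congo", 4), ("Iraq", 6), ("Libya", 2),
    ("Nigeria", 4), ("Pakistan", 3), ("South Sudan", 4), ("Sudan", 3),
]
_SHARED_COUNTRIES = ["Yemen", "Cameroon", "Ethiopia", "Niger", "Ukraine",
                     "Mali", "Somalia", "Turkey", "Colombia"]
_A_ONLY = ["Bangladesh", "Nepal", "Thailand", "Egypt", "Jordan"]
_B_ONLY = ["Papua New Guinea", "The Philippines", "West Bank and Gaza Strip",
           "Burkina Faso", "Chad", "Lebanon", "The Gambia", "Zimbabwe"]

# capital-city matched pairs (7) and adjudicated-possible pairs (4), by
# index into the country-expanded match list
_CAPITAL_MATCH_IDX = {0, 1, 7, 11, 12, 19, 26}
_POSSIBLE_MATCH_IDX = {4, 16, 25, 32}

#: events of the union universe per calendar month (sums to 254)
_MONTH_QUOTA = [21, 21, 21, 21, 21, 15, 15, 21, 21, 21, 22, 34]


def _expand(pairs: Sequence[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


class _FixtureBuilder:
    """Deterministic bookkeeping for the constructed fixture."""

    def __init__(self) -> None:
        self.site_serial: dict[str, int] = {}
        self.day_slot: dict[tuple[str, int], int] = {}

    def site(self, country: str) -> str:
        serial = self.site_serial.get(country, 0)
        self.site_serial[country] = serial + 1
        name = TOWN_NAMES[serial % len(TOWN_NAMES)]
        return name if serial < len(TOWN_NAMES) else f"{name} {serial // len(TOWN_NAMES)}"

    def slot_day(self, country: str, month: int) -> int:
        k = self.day_slot.get((country, month), 0)
        self.day_slot[(country, month)] = k + 1
        if k > 6:
            raise AssertionError(f"day-slot overflow in {country} month {month}")
        return 2 + 4 * k


def _month_sequence(quota: Sequence[int]) -> list[int]:
    remaining = list(quota)
    seq: list[int] = []
    while any(remaining):
        for month in range(12):
            if remaining[month] > 0:
                remaining[month] -= 1
                seq.append(month + 1)
    return seq


def make_paper_fixture(out_dir=None) -> FixtureBundle:
    """Build the deterministic two-source emulation fixture.

    Optionally writes the same file set as :func:`apply_noise_and_write`
    when ``out_dir`` is given. The construction is fixed — no sampling —
    so outputs are byte-identical across runs.
    """
    b = _FixtureBuilder()
    records_a: list[EventRecord] = []
    records_b: list[EventRecord] = []
    truth_pairs: list[tuple[str, str]] = []

    match_countries = _expand(_MATCH_COUNTRIES)
    n_matches = len(match_countries)  # 33

    # --- attribute sequences for matched pairs -------------------------
    ordinary_idx = [i for i in range(n_matches) if i not in _POSSIBLE_MATCH_IDX]
    match_type = {i: "personnel" for i in _POSSIBLE_MATCH_IDX}
    for i, t in zip(ordinary_idx,
                    _expand([("ambulance", 3), ("facility", 9),
                             ("personnel", 15), ("patient", 2)])):
        match_type[i] = t
    match_actor = {i: "none" for i in _POSSIBLE_MATCH_IDX}
    for i, actor in zip(ordinary_idx,
                        _expand([("msf_redcross", 9), ("other", 3), ("none", 17)])):
        match_actor[i] = actor

    # --- pseudo-pairs: possible matches adjudicated to unique ----------
    # one per month, in countries covered by both sources
    pseudo_specs = [(_MATCH_COUNTRIES[p % len(_MATCH_COUNTRIES)][0], p + 1)
                    for p in range(12)]
    pseudo_a: list[EventRecord] = []
    pseudo_b: list[EventRecord] = []

    month_quota = list(_MONTH_QUOTA)
    for country, month in pseudo_specs:
        month_quota[month - 1] -= 2
    month_seq = iter(_month_sequence(month_quota))

    # --- matched pairs ---------------------------------------------------
    a_serial = b_serial = 0
    for i, country in enumerate(match_countries):
        month = next(month_seq)
        day = b.slot_day(country, month)
        when = date(2017, month, day)
        a_serial += 1
        b_serial += 1
        rid_a, rid_b = f"A-{a_serial:04d}", f"B-{b_serial:04d}"
        if i in _CAPITAL_MATCH_IDX:
            location_a = location_b = CAPITALS[country]
        else:
            location_a = location_b = b.site(country)
        if i in _POSSIBLE_MATCH_IDX:
            # weaker agreement: exact date, dissimilar locations, near-equal
            # names -> graded possible, resolved by adjudication
            location_a = b.site(country)
            location_b = b.site(country)
            name_a = f"{b.site(country)} field hospital"
            name_b = name_a[:3] + name_a[4:]
        else:
            name_a = name_b = f"Unit {i:02d} medical centre"
        shared = dict(country=country, event_date=when, date_precision="day",
                      attack_type=match_type[i], named_actor=match_actor[i],
                      meets_definition=True)
        records_a.append(EventRecord(record_id=rid_a, source="A", setting="urban",
                                     location_name=location_a, entity_name=name_a,
                                     description="matched event", **shared))
        records_b.append(EventRecord(record_id=rid_b, source="B", setting="urban",
                                     location_name=location_b, entity_name=name_b,
                                     description="matched event", **shared))
        truth_pairs.append((rid_a, rid_b))

    # --- unique events ---------------------------------------------------
    a_countries = [c for c, _ in _MATCH_COUNTRIES] + _SHARED_COUNTRIES + _A_ONLY
    b_countries = [c for c, _ in _MATCH_COUNTRIES] + _SHARED_COUNTRIES + _B_ONLY

    def unique_record(source: str, serial: int, country: str, when: date,
                      attack_type: str, actor: str, setting: str,
                      location: Optional[str]) -> EventRecord:
        return EventRecord(
            record_id=f"{source}-{serial:04d}", source=source, country=country,
            event_date=when, date_precision="day", location_name=location,
            setting=setting, attack_type=attack_type, named_actor=actor,
            entity_name=None, meets_definition=True,
            description="unique event",
        )

    # pseudo-pair members first (they need coupled dates)
    for country, month in pseudo_specs:
        day = b.slot_day(country, month)
        a_serial += 1
        pseudo_a.append(unique_record("A", a_serial, country,
                                      date(2017, month, day), "personnel",
                                      "none", "urban", b.site(country)))
        b_serial += 1
        pseudo_b.append(unique_record("B", b_serial, country,
                                      date(2017, month, day + 1), "personnel",
                                      "none", "urban", b.site(country)))

    rest_a_types = _expand([("access_delivery", 2), ("ambulance", 17),
                            ("facility", 38), ("personnel", 59), ("patient", 4)])
    rest_b_types = _expand([("access_delivery", 29), ("ambulance", 6),
                            ("facility", 16), ("personnel", 22), ("patient", 4)])

    rest_a: list[EventRecord] = []
    for j, attack_type in enumerate(rest_a_types):
        country = a_countries[j % len(a_countries)]
        month = next(month_seq)
        day = b.slot_day(country, month)
        a_serial += 1
        rest_a.append(unique_record("A", a_serial, country, date(2017, month, day),
                                    attack_type, "msf_redcross" if j < 15 else "none",
                                    "urban", b.site(country)))
    rest_b: list[EventRecord] = []
    for j, attack_type in enumerate(rest_b_types):
        country = b_countries[j % len(b_countries)]
        month = next(month_seq)
        day = b.slot_day(country, month)
        b_serial += 1
        rest_b.append(unique_record("B", b_serial, country, date(2017, month, day),
                                    attack_type, "msf_redcross" if j < 14 else "none",
                                    "urban", b.site(country)))

    # settings / missing locations over the combined unique lists
    uniques_a = pseudo_a + rest_a            # 132
    uniques_b = pseudo_b + rest_b            # 89
    for pos, rec in enumerate(uniques_a):
        if pos >= 126:
            uniques_a[pos] = rec.copy(location_name=None, setting="unknown")
        elif pos >= 88:
            uniques_a[pos] = rec.copy(setting="rural")
    for pos, rec in enumerate(uniques_b):
        if pos >= 55:
            uniques_b[pos] = rec.copy(location_name=None, setting="unknown")
        elif pos >= 45:
            uniques_b[pos] = rec.copy(setting="rural")
    records_a.extend(uniques_a)
    records_b.extend(uniques_b)

    # --- excluded strata -------------------------------------------------
    def excluded_record(source: str, serial: int, country: str, index: int,
                        meets: bool, description: str) -> EventRecord:
        month = index % 12 + 1
        day = 2 + 4 * (index // 12)
        return EventRecord(
            record_id=f"{source}-{serial:04d}", source=source, country=country,
            event_date=date(2017, month, min(day, 28)), date_precision="day",
            location_name=b.site(country), setting="urban",
            attack_type="personnel", named_actor="none", entity_name=None,
            meets_definition=meets, description=description,
        )

    # definition failures: 16 in A (over its in-scope countries), 34 in B
    # (5 protests in Angola, 2 in Kenya, 27 elsewhere)
    per_country_idx: dict[tuple[str, str], int] = {}

    def next_idx(source: str, country: str) -> int:
        key = (source, country)
        per_country_idx[key] = per_country_idx.get(key, 0) + 1
        return per_country_idx[key] - 1

    for j in range(16):
        country = a_countries[j % len(a_countries)]
        a_serial += 1
        records_a.append(excluded_record("A", a_serial, country,
                                         next_idx("A", country) + 60,
                                         False, "did not meet attack definition"))
    for country in ["Angola"] * 5 + ["Kenya"] * 2:
        b_serial += 1
        records_b.append(excluded_record("B", b_serial, country,
                                         next_idx("B", country),
                                         False, "protest event"))
    for j in range(27):
        country = b_countries[j % len(b_countries)]
        b_serial += 1
        records_b.append(excluded_record("B", b_serial, country,
                                         next_idx("B", country) + 90,
                                         False, "did not meet attack definition"))

    # Syria (excluded country): 30 in A, 25 in B
    for j in range(30):
        a_serial += 1
        records_a.append(excluded_record("A", a_serial, "Syrian Arab Republic", j,
                                         True, "event in excluded country"))
    for j in range(25):
        b_serial += 1
        records_b.append(excluded_record("B", b_serial, "Syrian Arab Republic", j + 40,
                                         True, "event in excluded country"))

    # non-WHE countries: 51 events over 13 countries in A, 56 over 25 in B
    for j in range(51):
        country = NON_WHE_COUNTRIES[j % 13]
        a_serial += 1
        records_a.append(excluded_record("A", a_serial, country,
                                         next_idx("A", country), True,
                                         "event outside WHE scope"))
    for j in range(56):
        country = NON_WHE_COUNTRIES[j % 25]
        b_serial += 1
        records_b.append(excluded_record("B", b_serial, country,
                                         next_idx("B", country), True,
                                         "event outside WHE scope"))

    # planted duplicates: 2 in A, 1 in B, copies of included records
    records_a.append(records_a[0].copy(record_id="A-9001",
                                       description="duplicate report"))
    records_a.append(records_a[40].copy(record_id="A-9002",
                                        description="duplicate report"))
    records_b.append(records_b[0].copy(record_id="B-9001",
                                       description="duplicate report"))

    assert len(records_a) == 264 and len(records_b) == 238

    bundle = FixtureBundle(records_a=records_a, records_b=records_b,
                           truth_pairs=truth_pairs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_events(records_a, out_dir / "events_a.csv")
        write_events(records_b, out_dir / "events_b.csv")
        with (out_dir / "truth_key.csv").open("w", encoding="utf-8", newline="") as fh:
            fh.write("record_id_A,record_id_B,latent_event_id\n")
            for k, (rid_a, rid_b) in enumerate(truth_pairs):
                fh.write(f"{rid_a},{rid_b},{k}\n")
        with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
            json.dump({"fixture": "constructed-replication", "deterministic": True,
                       "n_records_a": len(records_a), "n_records_b": len(records_b),
                       "n_truth_pairs": len(truth_pairs)}, fh, indent=2)
            fh.write("\n")
    return bundle
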