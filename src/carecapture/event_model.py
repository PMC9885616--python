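"""Normalised event records and the WHE country registry.

Every stage of the pipeline works on :class:`EventRecord` objects: one row
per publicly-reported attack on health care, with the comparison-ready
fields (date, country, sub-national location, facility/victim name) plus
the coder flags that drive inclusion filtering.

Geographic scope is defined by the WHO Health Emergencies (WHE) programme
country list for 2016: 47 countries/territories across grade 1-3
emergencies and non-graded protracted emergencies. The Syrian Arab Republic
is on the list but is excluded from analysis (double counting cannot be
ruled out there), so country status is three-valued: in scope, explicitly
excluded, or outside the WHE framework.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterable, Mapping, Optional

from dateutil import parser as _dateparser

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

SOURCES = ("A", "B")

DATE_PRECISIONS = ("day", "month", "unknown")

SETTINGS = ("urban", "rural", "unknown")

#: The five attack categories, in report order.
ATTACK_TYPES = (
    "access_delivery",   # affecting only access to or delivery of health care
    "ambulance",         # affecting ambulances / medical transport
    "facility",          # affecting health facilities
    "personnel",         # affecting medical personnel
    "patient",           # affecting patients
)

NAMED_ACTORS = ("msf_redcross", "other", "none")

#: Grades in the WHE framework.
GRADES = ("grade3", "grade2", "grade1", "protracted")


class SchemaError(ValueError):
    """Raised when input rows or files violate the event schema."""


class UnknownCountryError(ValueError):
    """Raised when a record carries no usable country name."""


# ---------------------------------------------------------------------------
# EventRecord
# ---------------------------------------------------------------------------

@dataclass
class EventRecord:
    """One normalised reported attack.

    Absent free-text fields are ``None``, never the empty string. The
    date/precision pair is coupled: ``event_date`` is present iff
    ``date_precision`` is ``day`` or ``month``; month-precision dates are
    stored as the first of the month.
    """

    record_id: str
    source: str
    country: str
    event_date: Optional[date] = None
    date_precision: str = "unknown"
    location_name: Optional[str] = None
    setting: str = "unknown"
    attack_type: str = "personnel"
    named_actor: str = "none"
    entity_name: Optional[str] = None
    meets_definition: bool = True
    is_aggregated_report: bool = False
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise SchemaError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.date_precision not in DATE_PRECISIONS:
            raise SchemaError(f"bad date_precision {self.date_precision!r}")
        if (self.event_date is None) != (self.date_precision == "unknown"):
            raise SchemaError(
                f"record {self.record_id}: event_date present iff precision != unknown"
            )
        if self.setting not in SETTINGS:
            raise SchemaError(f"bad setting {self.setting!r}")
        if self.attack_type not in ATTACK_TYPES:
            raise SchemaError(f"bad attack_type {self.attack_type!r}")
        if self.named_actor not in NAMED_ACTORS:
            raise SchemaError(f"bad named_actor {self.named_actor!r}")
        if not self.record_id:
            raise SchemaError("record_id must be non-empty")

    def copy(self, **changes) -> "EventRecord":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# WHE country registry (2016 list)
# ---------------------------------------------------------------------------

_GRADE3 = (
    "Iraq",
    "Nigeria",
    "South Sudan",
    "Syrian Arab Republic",
    "Yemen",
)

_GRADE2 = (
    "Angola",
    "Cameroon",
    "Central African Republic",
    "Democratic Republic of the Congo",
    "Ecuador",
    "Ethiopia",
    "Haiti",
    "Libya",
    "Myanmar",
    "Niger",
    "Ukraine",
    "United Republic of Tanzania",
)

_GRADE1 = (
    "Afghanistan",
    "Bangladesh",
    "Democratic People's Republic of Korea",
    "Fiji",
    "Indonesia",
    "Kenya",
    "Mali",
    "Nepal",
    "Pakistan",
    "Papua New Guinea",
    "Sri Lanka",
    "Thailand",
    "The Philippines",
    "West Bank and Gaza Strip",
)

_PROTRACTED = (
    "Burkina Faso",
    "Chad",
    "Colombia",
    "Djibouti",
    "Egypt",
    "Guatemala",
    "Honduras",
    "Jordan",
    "Lebanon",
    "Mauritania",
    "Senegal",
    "Somalia",
    "Sudan",
    "The Gambia",
    "Turkey",
    "Zimbabwe",
)

#: Common variants -> canonical registry spelling.
COUNTRY_ALIASES: dict[str, str] = {
    "drc": "Democratic Republic of the Congo",
    "dr congo": "Democratic Republic of the Congo",
    "congo, democratic republic of the": "Democratic Republic of the Congo",
    "democratic republic of congo": "Democratic Republic of the Congo",
    "car": "Central African Republic",
    "dprk": "Democratic People's Republic of Korea",
    "north korea": "Democratic People's Republic of Korea",
    "syria": "Syrian Arab Republic",
    "opt": "West Bank and Gaza Strip",
    "occupied palestinian territory": "West Bank and Gaza Strip",
    "palestine": "West Bank and Gaza Strip",
    "philippines": "The Philippines",
    "gambia": "The Gambia",
    "tanzania": "United Republic of Tanzania",
    "turkiye": "Turkey",
    "burma": "Myanmar",
}

#: Capital city per WHE country, used to flag matched events in capital
#: cities in the descriptive location breakdown.
CAPITALS: dict[str, str] = {
    "Iraq": "Baghdad",
    "Nigeria": "Abuja",
    "South Sudan": "Juba",
    "Syrian Arab Republic": "Damascus",
    "Yemen": "Sanaa",
    "Angola": "Luanda",
    "Cameroon": "Yaounde",
    "Central African Republic": "Bangui",
    "Democratic Republic of the Congo": "Kinshasa",
    "Ecuador": "Quito",
    "Ethiopia": "Addis Ababa",
    "Haiti": "Port-au-Prince",
    "Libya": "Tripoli",
    "Myanmar": "Naypyidaw",
    "Niger": "Niamey",
    "Ukraine": "Kyiv",
    "United Republic of Tanzania": "Dodoma",
    "Afghanistan": "Kabul",
    "Bangladesh": "Dhaka",
    "Democratic People's Republic of Korea": "Pyongyang",
    "Fiji": "Suva",
    "Indonesia": "Jakarta",
    "Kenya": "Nairobi",
    "Mali": "Bamako",
    "Nepal": "Kathmandu",
    "Pakistan": "Islamabad",
    "Papua New Guinea": "Port Moresby",
    "Sri Lanka": "Colombo",
    "Thailand": "Bangkok",
    "The Philippines": "Manila",
    "West Bank and Gaza Strip": "Ramallah",
    "Burkina Faso": "Ouagadougou",
    "Chad": "N'Djamena",
    "Colombia": "Bogota",
    "Djibouti": "Djibouti",
    "Egypt": "Cairo",
    "Guatemala": "Guatemala City",
    "Honduras": "Tegucigalpa",
    "Jordan": "Amman",
    "Lebanon": "Beirut",
    "Mauritania": "Nouakchott",
    "Senegal": "Dakar",
    "Somalia": "Mogadishu",
    "Sudan": "Khartoum",
    "The Gambia": "Banjul",
    "Turkey": "Ankara",
    "Zimbabwe": "Harare",
}


@dataclass(frozen=True)
class CountryRegistry:
    """The WHE country list with per-country grade and exclusions."""

    entries: dict[str, str] = field(default_factory=dict)  # name -> grade
    excluded: frozenset[str] = frozenset()

    @classmethod
    def whe_2016(cls) -> "CountryRegistry":
        entries: dict[str, str] = {}
        for grade, names in (
            ("grade3", _GRADE3),
            ("grade2", _GRADE2),
            ("grade1", _GRADE1),
            ("protracted", _PROTRACTED),
        ):
            for name in names:
                entries[name] = grade
        return cls(entries=entries, excluded=frozenset({"Syrian Arab Republic"}))

    def __len__(self) -> int:
        return len(self.entries)

    def grade_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GRADES}
        for grade in self.entries.values():
            counts[grade] += 1
        return counts

    def in_scope_countries(self) -> set[str]:
        return {c for c in self.entries if c not in self.excluded}


def country_status(country: str, registry: CountryRegistry) -> str:
    """Classify a canonical country name for study scope.

    Returns ``"in_scope"`` (WHE-listed, analysed), ``"excluded"``
    (WHE-listed but excluded, i.e. Syria), or ``"non_whe"``.
    """
    if country in registry.excluded:
        return "excluded"
    if country in registry.entries:
        return "in_scope"
    return "non_whe"


def canonical_country(name: str) -> str:
    """Map a country spelling to its canonical registry form.

    Unknown names are returned verbatim (they will classify as non-WHE);
    only an empty name is an error.
    """
    if name is None or not str(name).strip():
        raise UnknownCountryError("country name is missing")
    cleaned = " ".join(str(name).split())
    key = cleaned.casefold().rstrip(".")
    if key in COUNTRY_ALIASES:
        return COUNTRY_ALIASES[key]
    registry = CountryRegistry.whe_2016()
    for canon in registry.entries:
        if canon.casefold() == key:
            return canon
    return cleaned


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def _parse_bool(value: Optional[str], default: bool) -> bool:
    if value is None or str(value).strip() == "":
        return default
    v = str(value).strip().casefold()
    if v in ("true", "1", "yes", "y"):
        return True
    if v in ("false", "0", "no", "n"):
        return False
    raise SchemaError(f"cannot parse boolean value {value!r}")


def parse_event_date(text: Optional[str]) -> tuple[Optional[date], str]:
    """Parse a free-form date string to (date, precision).

    Day precision when a day-of-month is present; month precision when
    only year+month can be resolved (stored as the first of the month);
    ``(None, "unknown")`` when the text is absent or unparseable.
    """
    if text is None or not str(text).strip():
        return None, "unknown"
    s = str(text).strip()
    # Two sentinel defaults: components that differ between the two parses
    # were defaulted, i.e. absent from the input.
    d1 = datetime(2001, 1, 1)
    d2 = datetime(2002, 2, 2)
    try:
        p1 = _dateparser.parse(s, default=d1)
        p2 = _dateparser.parse(s, default=d2)
    except (ValueError, OverflowError):
        return None, "unknown"
    if p1.year != p2.year or p1.month != p2.month:
        return None, "unknown"
    if p1.day != p2.day:
        return date(p1.year, p1.month, 1), "month"
    return p1.date(), "day"


def _clean_text(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    cleaned = " ".join(str(value).split())
    return cleaned or None


def normalize_event(raw_fields: Mapping[str, Optional[str]], *, warnings: Optional[list] = None) -> EventRecord:
    """Build a normalised :class:`EventRecord` from raw CSV fields.

    Required keys: ``record_id``, ``source``, ``country``. Dates are parsed
    leniently; an unparseable date keeps the record with unknown precision
    and appends a warning to ``warnings`` (when given). Absent optional
    fields become ``None`` / ``unknown``, never empty strings.
    """
    for key in ("record_id", "source", "country"):
        if key not in raw_fields or not _clean_text(raw_fields.get(key)):
            if key == "country":
                rid = _clean_text(raw_fields.get("record_id")) or "<unknown>"
                raise UnknownCountryError(f"record {rid}: country is missing")
            raise SchemaError(f"missing required field {key!r}")

    record_id = _clean_text(raw_fields["record_id"])
    source = _clean_text(raw_fields["source"])
    country = canonical_country(raw_fields["country"])

    raw_date = raw_fields.get("event_date")
    event_date, precision = parse_event_date(raw_date)
    if event_date is None and _clean_text(raw_date) is not None and warnings is not None:
        warnings.append(f"record {record_id}: unparseable date {raw_date!r}; precision set to unknown")

    setting = _clean_text(raw_fields.get("setting")) or "unknown"
    attack_type = _clean_text(raw_fields.get("attack_type")) or "personnel"
    named_actor = _clean_text(raw_fields.get("named_actor")) or "none"

    return EventRecord(
        record_id=record_id,
        source=source,
        country=country,
        event_date=event_date,
        date_precision=precision,
        location_name=_clean_text(raw_fields.get("location_name")),
        setting=setting.casefold(),
        attack_type=attack_type.casefold(),
        named_actor=named_actor.casefold(),
        entity_name=_clean_text(raw_fields.get("entity_name")),
        meets_definition=_parse_bool(raw_fields.get("meets_definition"), True),
        is_aggregated_report=_parse_bool(raw_fields.get("is_aggregated_report"), False),
        description=_clean_text(raw_fields.get("description")),
    )


def strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize_compare_text(text: str) -> str:
    """Case-fold, strip diacritics and collapse whitespace for comparison."""
    return " ".join(strip_diacritics(text).casefold().split())
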