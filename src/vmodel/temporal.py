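"""Granularity-aware temporal anchors and interval reasoning.

Narrative clinical text rarely states calendar dates precisely.  A discharge
summary may say ``'86``, ``02.8``, ``from late 02.7``, ``three days ago`` or
simply ``postop``.  This module maps each such *temporal anchor point* (TAP)
expression onto a calendar interval of possible times — the whole of 1986 for
``'86``, August 2002 for ``02.8`` — and reasons over those intervals:

* :func:`parse_tap` resolves an expression to a :class:`TemporalAnchor`
  (kind, granularity, fuzzy modifier, open start, interval).  It is total:
  anything it cannot resolve becomes a *proximity hint* whose verbatim text
  is preserved, never an error.
* :func:`distance_bounds` computes the range of possible elapsed time
  between two anchors, e.g. 188–199 months between ``'86`` and ``02.8``
  (15 y 8 m to 16 y 7 m).
* :func:`distance_estimate` rounds the midpoint of those bounds to whole
  years ("about sixteen years").
* :func:`qualitative_relation` decides before / after / same-expression /
  undetermined from the interval endpoints.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum
from typing import TYPE_CHECKING, Mapping, Optional

if TYPE_CHECKING:  # pragma: no cover - only for type hints
    from .model import ClinicalEvent, VStructure

__all__ = [
    "AnchorKind",
    "CalendarInterval",
    "Dialect",
    "DurationBounds",
    "FuzzyModifier",
    "Granularity",
    "Relation",
    "TemporalAnchor",
    "Unit",
    "UnresolvedAnchorError",
    "distance_bounds",
    "distance_estimate",
    "parse_tap",
    "problem_precedes_action",
    "qualitative_relation",
]


class Granularity(str, Enum):
    """Calendar resolution of a temporal expression."""

    DECADE = "decade"
    YEAR = "year"
    MONTH = "month"
    DAY = "day"
    HOUR = "hour"
    MINUTE = "minute"
    UNKNOWN = "unknown"


#: ordering from coarse to fine, used when picking a distance unit
_GRANULARITY_ORDER = [
    Granularity.DECADE,
    Granularity.YEAR,
    Granularity.MONTH,
    Granularity.DAY,
    Granularity.HOUR,
    Granularity.MINUTE,
]


class AnchorKind(str, Enum):
    ABSOLUTE = "absolute"
    RELATIVE = "relative"
    PROXIMITY_HINT = "proximity_hint"
    MISSING = "missing"


class FuzzyModifier(str, Enum):
    NONE = "none"
    EARLY = "early"
    MID = "mid"
    LATE = "late"


class Unit(str, Enum):
    YEARS = "years"
    MONTHS = "months"
    DAYS = "days"
    HOURS = "hours"
    MINUTES = "minutes"


class Relation(str, Enum):
    BEFORE = "before"
    AFTER = "after"
    SAME_EXPRESSION = "same_expression"
    UNDETERMINED = "undetermined"


class UnresolvedAnchorError(ValueError):
    """Raised when interval arithmetic is asked of an anchor without one."""


@dataclass(frozen=True)
class CalendarInterval:
    """Closed interval of possible times, at minute resolution."""

    earliest: datetime
    latest: datetime

    def __post_init__(self) -> None:
        if self.earliest > self.latest:
            raise ValueError("interval earliest must not exceed latest")


@dataclass(frozen=True)
class TemporalAnchor:
    """A TAP: the verbatim expression plus its resolved possible-time span.

    ``interval`` is absent for proximity hints ("postop"), missing
    expressions, and relative expressions that lack an anchor date.
    """

    raw_text: str
    kind: AnchorKind
    granularity: Granularity = Granularity.UNKNOWN
    fuzzy_modifier: FuzzyModifier = FuzzyModifier.NONE
    open_start: bool = False
    interval: Optional[CalendarInterval] = None


@dataclass(frozen=True)
class DurationBounds:
    """Possible elapsed time between two anchors, in whole units."""

    min_units: int
    max_units: int
    unit: Unit

    def __post_init__(self) -> None:
        if self.min_units < 0 or self.min_units > self.max_units:
            raise ValueError("require 0 <= min_units <= max_units")


@dataclass(frozen=True)
class Dialect:
    """Configurable conventions of the temporal expression dialect.

    century_pivot
        Two-digit years >= pivot resolve to 19YY, below it to 20YY
        (pivot 30: '86 -> 1986, '02 -> 2002).
    lexicon
        Optional mapping of named-day expressions (casefolded) to an
        expression the dialect can parse (e.g. a "Korean Thanksgiving Day"
        entry mapping to "02.9.21").  Unmapped names stay proximity hints so
        their contextual meaning is not discarded.
    """

    century_pivot: int = 30
    lexicon: Mapping[str, str] = field(default_factory=dict)


_DEFAULT_DIALECT = Dialect()

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "a": 1, "an": 1,
}

_RE_YEAR = re.compile(r"^'?(\d{2}|\d{4})$")
_RE_DECADE = re.compile(r"^'?(\d{2}|\d{4})s$")
_RE_MONTH = re.compile(r"^'?(\d{2}|\d{4})[.\-/](\d{1,2})$")
_RE_DAY = re.compile(r"^'?(\d{2}|\d{4})[.\-/](\d{1,2})[.\-/](\d{1,2})$")
_RE_MINUTE = re.compile(
    r"^(\d{4})-(\d{1,2})-(\d{1,2})[T ](\d{1,2}):(\d{2})$"
)
_RE_RELATIVE = re.compile(
    r"^(\d+|[a-z]+)\s+(year|month|week|day|hour|minute)s?\s+(ago|before|earlier)$"
)
_RE_FUZZY = re.compile(r"^(early|mid|late)\s+(.+)$")
_RE_OPEN = re.compile(r"^(?:since|from)\s+(.+)$")


def _resolve_year(two_or_four: str, pivot: int) -> int:
    value = int(two_or_four)
    if len(two_or_four) == 4:
        return value
    return 1900 + value if value >= pivot else 2000 + value


def _year_interval(year: int) -> CalendarInterval:
    return CalendarInterval(datetime(year, 1, 1, 0, 0),
                            datetime(year, 12, 31, 23, 59))


def _month_interval(year: int, month: int) -> CalendarInterval:
    last = calendar.monthrange(year, month)[1]
    return CalendarInterval(datetime(year, month, 1, 0, 0),
                            datetime(year, month, last, 23, 59))


def _day_interval(day: date) -> CalendarInterval:
    return CalendarInterval(datetime(day.year, day.month, day.day, 0, 0),
                            datetime(day.year, day.month, day.day, 23, 59))


def _apply_fuzzy(interval: CalendarInterval,
                 modifier: FuzzyModifier) -> CalendarInterval:
    """Narrow an interval to its early / mid / late third (by minutes)."""
    if modifier is FuzzyModifier.NONE:
        return interval
    total = int((interval.latest - interval.earliest).total_seconds() // 60) + 1
    third = total // 3
    if third == 0:
        return interval
    if modifier is FuzzyModifier.EARLY:
        return CalendarInterval(
            interval.earliest,
            interval.earliest + timedelta(minutes=third - 1))
    if modifier is FuzzyModifier.LATE:
        return CalendarInterval(
            interval.latest - timedelta(minutes=third - 1),
            interval.latest)
    return CalendarInterval(
        interval.earliest + timedelta(minutes=third),
        interval.latest - timedelta(minutes=third))


def _to_datetime(anchor_date: "date | datetime") -> datetime:
    if isinstance(anchor_date, datetime):
        return anchor_date.replace(second=0, microsecond=0)
    return datetime(anchor_date.year, anchor_date.month, anchor_date.day)


def parse_tap(raw_text: str,
              anchor_date: "date | datetime | None" = None,
              dialect: Dialect | None = None) -> TemporalAnchor:
    """Resolve a temporal expression into a :class:`TemporalAnchor`.

    Total over all strings: empty input yields a *missing* anchor and any
    unrecognised expression a *proximity hint*; nothing raises.
    ``anchor_date`` is needed only for relative forms ("three days ago");
    without it those stay unresolved (kind relative, no interval).
    """
    dialect = dialect or _DEFAULT_DIALECT
    raw = raw_text or ""
    text = raw.strip()
    if not text:
        return TemporalAnchor(raw, AnchorKind.MISSING)

    lowered = text.casefold()
    if lowered in dialect.lexicon:
        mapped = parse_tap(dialect.lexicon[lowered], anchor_date, dialect)
        if mapped.interval is not None:
            return TemporalAnchor(raw, mapped.kind, mapped.granularity,
                                  mapped.fuzzy_modifier, mapped.open_start,
                                  mapped.interval)
        return TemporalAnchor(raw, AnchorKind.PROXIMITY_HINT)

    open_start = False
    m = _RE_OPEN.match(lowered)
    body = lowered
    if m:
        open_start = True
        body = m.group(1).strip()

    modifier = FuzzyModifier.NONE
    m = _RE_FUZZY.match(body)
    if m:
        modifier = FuzzyModifier(m.group(1))
        body = m.group(2).strip()

    parsed = _parse_core(body, anchor_date, dialect)
    if parsed is None:
        if open_start or modifier is not FuzzyModifier.NONE:
            # "since <unparseable>" still carries proximity information
            return TemporalAnchor(raw, AnchorKind.PROXIMITY_HINT)
        return TemporalAnchor(raw, AnchorKind.PROXIMITY_HINT)
    kind, granularity, interval = parsed
    if interval is not None:
        interval = _apply_fuzzy(interval, modifier)
    return TemporalAnchor(raw, kind, granularity, modifier, open_start,
                          interval)


def _parse_core(body: str,
                anchor_date: "date | datetime | None",
                dialect: Dialect
                ) -> "tuple[AnchorKind, Granularity, CalendarInterval | None] | None":
    m = _RE_MINUTE.match(body)
    if m:
        y, mo, d, h, mi = (int(g) for g in m.groups())
        try:
            stamp = datetime(y, mo, d, h, mi)
        except ValueError:
            return None
        return (AnchorKind.ABSOLUTE, Granularity.MINUTE,
                CalendarInterval(stamp, stamp))

    m = _RE_DECADE.match(body)
    if m:
        year = _resolve_year(m.group(1), dialect.century_pivot)
        start = year - year % 10
        return (AnchorKind.ABSOLUTE, Granularity.DECADE,
                CalendarInterval(datetime(start, 1, 1),
                                 datetime(start + 9, 12, 31, 23, 59)))

    m = _RE_DAY.match(body)
    if m:
        year = _resolve_year(m.group(1), dialect.century_pivot)
        try:
            day = date(year, int(m.group(2)), int(m.group(3)))
        except ValueError:
            return None
        return (AnchorKind.ABSOLUTE, Granularity.DAY, _day_interval(day))

    m = _RE_MONTH.match(body)
    if m:
        year = _resolve_year(m.group(1), dialect.century_pivot)
        month = int(m.group(2))
        if not 1 <= month <= 12:
            return None
        return (AnchorKind.ABSOLUTE, Granularity.MONTH,
                _month_interval(year, month))

    m = _RE_YEAR.match(body)
    if m:
        year = _resolve_year(m.group(1), dialect.century_pivot)
        return (AnchorKind.ABSOLUTE, Granularity.YEAR, _year_interval(year))

    m = _RE_RELATIVE.match(body)
    if m:
        count_text, unit, _ = m.groups()
        if count_text.isdigit():
            count = int(count_text)
        elif count_text in _NUMBER_WORDS:
            count = _NUMBER_WORDS[count_text]
        else:
            return None
        if anchor_date is None:
            granularity = (Granularity.DAY if unit == "week"
                           else Granularity(unit))
            return (AnchorKind.RELATIVE, granularity, None)
        ref = _to_datetime(anchor_date)
        if unit == "year":
            try:
                target = ref.replace(year=ref.year - count)
            except ValueError:  # Feb 29
                target = ref.replace(year=ref.year - count, day=28)
            return (AnchorKind.RELATIVE, Granularity.YEAR,
                    _year_interval(target.year))
        if unit == "month":
            months = ref.year * 12 + (ref.month - 1) - count
            return (AnchorKind.RELATIVE, Granularity.MONTH,
                    _month_interval(months // 12, months % 12 + 1))
        if unit in ("day", "week"):
            days = count * (7 if unit == "week" else 1)
            return (AnchorKind.RELATIVE, Granularity.DAY,
                    _day_interval((ref - timedelta(days=days)).date()))
        if unit == "hour":
            stamp = (ref - timedelta(hours=count)).replace(minute=0)
            return (AnchorKind.RELATIVE, Granularity.HOUR,
                    CalendarInterval(stamp, stamp + timedelta(minutes=59)))
        stamp = ref - timedelta(minutes=count)
        return (AnchorKind.RELATIVE, Granularity.MINUTE,
                CalendarInterval(stamp, stamp))

    return None


# ---------------------------------------------------------------------------
# interval reasoning

def _require_interval(anchor: TemporalAnchor, which: str) -> CalendarInterval:
    if anchor.interval is None:
        raise UnresolvedAnchorError(
            f"unresolved anchor: argument {which!r} ({anchor.raw_text!r}, "
            f"kind={anchor.kind.value}) has no calendar interval")
    return anchor.interval


def _distance_unit(a: TemporalAnchor, b: TemporalAnchor) -> Unit:
    """Finer of the two granularities, floored at month.

    Year- or decade-level anchors still span many months, so distances
    involving them are reported in months (the printed 15y8m-16y7m range for
    a year/month pair follows this convention); finer pairs use their own
    resolution.
    """
    levels = []
    for anchor in (a, b):
        g = anchor.granularity
        idx = _GRANULARITY_ORDER.index(g) if g in _GRANULARITY_ORDER else 2
        levels.append(max(idx, _GRANULARITY_ORDER.index(Granularity.MONTH)))
    finest = _GRANULARITY_ORDER[max(levels)]
    return {
        Granularity.MONTH: Unit.MONTHS,
        Granularity.DAY: Unit.DAYS,
        Granularity.HOUR: Unit.HOURS,
        Granularity.MINUTE: Unit.MINUTES,
    }[finest]


def _truncate_index(stamp: datetime, unit: Unit) -> int:
    """Integer index of the unit-sized bin containing ``stamp``."""
    if unit is Unit.YEARS:
        return stamp.year
    if unit is Unit.MONTHS:
        return stamp.year * 12 + (stamp.month - 1)
    days = stamp.date().toordinal()
    if unit is Unit.DAYS:
        return days
    hours = days * 24 + stamp.hour
    if unit is Unit.HOURS:
        return hours
    return hours * 60 + stamp.minute


def distance_bounds(a: TemporalAnchor, b: TemporalAnchor) -> DurationBounds:
    """Possible elapsed time from ``a`` to ``b`` in whole units.

    Both endpoints are truncated to the distance unit before subtraction;
    callers pass the earlier anchor first.  For ``'86`` and ``02.8`` this
    yields 188-199 months.
    """
    ia = _require_interval(a, "a")
    ib = _require_interval(b, "b")
    unit = _distance_unit(a, b)
    lo = _truncate_index(ib.earliest, unit) - _truncate_index(ia.latest, unit)
    hi = _truncate_index(ib.latest, unit) - _truncate_index(ia.earliest, unit)
    return DurationBounds(max(0, lo), max(0, hi), unit)


_MINUTES_PER_YEAR = 365.25 * 24 * 60

_UNIT_IN_YEARS = {
    Unit.YEARS: 1.0,
    Unit.MONTHS: 1.0 / 12.0,
    Unit.DAYS: 1.0 / 365.25,
    Unit.HOURS: 1.0 / (365.25 * 24),
    Unit.MINUTES: 1.0 / _MINUTES_PER_YEAR,
}


def distance_estimate(a: TemporalAnchor, b: TemporalAnchor) -> int:
    """Midpoint of :func:`distance_bounds` in whole years, rounded half-up.

    The 188-199 month range between ``'86`` and ``02.8`` has midpoint 193.5
    months = 16.125 years, i.e. "about sixteen years".
    """
    bounds = distance_bounds(a, b)
    midpoint = (bounds.min_units + bounds.max_units) / 2.0
    years = midpoint * _UNIT_IN_YEARS[bounds.unit]
    return int(years + 0.5)


def qualitative_relation(a: TemporalAnchor, b: TemporalAnchor) -> Relation:
    """Allen-style coarse relation between two anchors.

    ``before``/``after`` require strictly disjoint intervals; anchors with
    the same verbatim expression (sharing one TAP) report
    ``same_expression``; everything else — overlap, missing intervals,
    proximity hints — is ``undetermined``.
    """
    same_raw = bool(a.raw_text.strip()) and a.raw_text == b.raw_text
    if same_raw and a.kind == b.kind:
        return Relation.SAME_EXPRESSION
    if a.interval is None or b.interval is None:
        return Relation.UNDETERMINED
    if a.interval.latest < b.interval.earliest:
        return Relation.BEFORE
    if b.interval.latest < a.interval.earliest:
        return Relation.AFTER
    return Relation.UNDETERMINED


def problem_precedes_action(v: "VStructure", p: "ClinicalEvent",
                            a: "ClinicalEvent") -> bool:
    """The within-structure axiom: a problem starts before its actions.

    Holds by construction for any problem/action pair of one v-structure,
    even when both carry the same temporal expression (the chief complaint
    precedes the tests ordered for it).  Membership is enforced.
    """
    if p not in v.problems:
        raise ValueError(f"event {p.event_id!r} is not on the Problem wing "
                         f"of structure {v.structure_id!r}")
    if a not in v.actions:
        raise ValueError(f"event {a.event_id!r} is not on the Action wing "
                         f"of structure {v.structure_id!r}")
    return True
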