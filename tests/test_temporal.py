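"""Temporal anchor parsing and interval reasoning."""

from datetime import date, datetime

import pytest
from hypothesis import given, settings, strategies as st

from vmodel.temporal import (AnchorKind, Dialect, FuzzyModifier, Granularity,
                             Relation, TemporalAnchor, Unit,
                             UnresolvedAnchorError, distance_bounds,
                             distance_estimate, parse_tap,
                             problem_precedes_action, qualitative_relation)


# ---------------------------------------------------------------------------
# independent oracle: endpoint enumeration with its own truncation scheme

def _truncate(stamp: datetime, unit: Unit) -> int:
    table = {
        Unit.MONTHS: lambda s: (s.year - 1) * 12 + (s.month - 1),
        Unit.DAYS: lambda s: s.date().toordinal(),
        Unit.HOURS: lambda s: s.date().toordinal() * 24 + s.hour,
        Unit.MINUTES: lambda s: (s.date().toordinal() * 24 + s.hour) * 60
        + s.minute,
    }
    return table[unit](stamp)


def oracle_bounds(a: TemporalAnchor, b: TemporalAnchor, unit: Unit):
    """Min/max whole-unit difference over all four endpoint combinations."""
    diffs = [_truncate(tb, unit) - _truncate(ta, unit)
             for ta in (a.interval.earliest, a.interval.latest)
             for tb in (b.interval.earliest, b.interval.latest)]
    return max(0, min(diffs)), max(0, max(diffs))


def oracle_relation(a: TemporalAnchor, b: TemporalAnchor) -> Relation:
    if a.interval is None or b.interval is None:
        return Relation.UNDETERMINED
    if a.interval.latest < b.interval.earliest:
        return Relation.BEFORE
    if b.interval.latest < a.interval.earliest:
        return Relation.AFTER
    return Relation.UNDETERMINED


# ---------------------------------------------------------------------------
# parsing

@pytest.mark.parametrize("raw, kind, granularity, earliest, latest", [
    ("86", AnchorKind.ABSOLUTE, Granularity.YEAR,
     datetime(1986, 1, 1, 0, 0), datetime(1986, 12, 31, 23, 59)),
    ("02.8", AnchorKind.ABSOLUTE, Granularity.MONTH,
     datetime(2002, 8, 1, 0, 0), datetime(2002, 8, 31, 23, 59)),
    ("2002", AnchorKind.ABSOLUTE, Granularity.YEAR,
     datetime(2002, 1, 1, 0, 0), datetime(2002, 12, 31, 23, 59)),
    ("02.8.4", AnchorKind.ABSOLUTE, Granularity.DAY,
     datetime(2002, 8, 4, 0, 0), datetime(2002, 8, 4, 23, 59)),
    ("1980s", AnchorKind.ABSOLUTE, Granularity.DECADE,
     datetime(1980, 1, 1, 0, 0), datetime(1989, 12, 31, 23, 59)),
])
def test_parse_absolute_forms(raw, kind, granularity, earliest, latest):
    anchor = parse_tap(raw)
    assert anchor.kind is kind
    assert anchor.granularity is granularity
    assert anchor.interval.earliest == earliest
    assert anchor.interval.latest == latest
    assert anchor.raw_text == raw


def test_century_pivot_reproduces_printed_years():
    assert parse_tap("86").interval.earliest.year == 1986
    assert parse_tap("02").interval.earliest.year == 2002
    assert parse_tap("29").interval.earliest.year == 2029
    assert parse_tap("30").interval.earliest.year == 1930


def test_semi_interval_fuzzy_expression():
    anchor = parse_tap("from late 02.7")
    assert anchor.kind is AnchorKind.ABSOLUTE
    assert anchor.granularity is Granularity.MONTH
    assert anchor.fuzzy_modifier is FuzzyModifier.LATE
    assert anchor.open_start is True
    # final third of July 2002
    assert anchor.interval.earliest >= datetime(2002, 7, 21)
    assert anchor.interval.latest == datetime(2002, 7, 31, 23, 59)


def test_fuzzy_thirds_partition_the_parent_unit():
    early = parse_tap("early 02.7").interval
    mid = parse_tap("mid 02.7").interval
    late = parse_tap("late 02.7").interval
    whole = parse_tap("02.7").interval
    assert early.earliest == whole.earliest
    assert late.latest == whole.latest
    assert early.latest < mid.earliest <= mid.latest < late.earliest


def test_relative_expression_resolved_against_anchor_date():
    anchor = parse_tap("three days ago", date(2002, 8, 15))
    assert anchor.kind is AnchorKind.RELATIVE
    assert anchor.granularity is Granularity.DAY
    assert anchor.interval.earliest == datetime(2002, 8, 12, 0, 0)
    assert anchor.interval.latest == datetime(2002, 8, 12, 23, 59)


def test_relative_without_anchor_date_stays_unresolved():
    anchor = parse_tap("three days ago")
    assert anchor.kind is AnchorKind.RELATIVE
    assert anchor.interval is None


def test_uneven_granularity_pair_from_one_narrative():
    # "Seizure increased since three days ago. Since two hours before,
    # respiration rate increased" — both resolve in one view
    ref = datetime(2002, 8, 15, 14, 30)
    days = parse_tap("since three days ago", ref)
    hours = parse_tap("since two hours before", ref)
    assert days.granularity is Granularity.DAY and days.open_start
    assert hours.granularity is Granularity.HOUR and hours.open_start
    assert hours.interval.earliest == datetime(2002, 8, 15, 12, 0)


def test_proximity_hint_and_missing():
    hint = parse_tap("postop")
    assert hint.kind is AnchorKind.PROXIMITY_HINT
    assert hint.interval is None
    assert hint.raw_text == "postop"
    assert parse_tap("").kind is AnchorKind.MISSING
    assert parse_tap("   ").kind is AnchorKind.MISSING


def test_named_day_lexicon_resolves_otherwise_hinted_expression():
    name = "Korean Thanksgiving Day"
    assert parse_tap(name).kind is AnchorKind.PROXIMITY_HINT
    dialect = Dialect(lexicon={name.casefold(): "02.9.21"})
    anchor = parse_tap(name, dialect=dialect)
    assert anchor.kind is AnchorKind.ABSOLUTE
    assert anchor.granularity is Granularity.DAY
    assert anchor.raw_text == name


@settings(derandomize=True, max_examples=300)
@given(st.text(max_size=30))
def test_parse_tap_is_total(raw):
    anchor = parse_tap(raw)
    assert anchor.kind in AnchorKind
    if anchor.kind is AnchorKind.PROXIMITY_HINT:
        assert anchor.raw_text.strip()


# ---------------------------------------------------------------------------
# distance reasoning

def test_worked_example_distance_bounds_and_estimate():
    """'86 to 02.8 spans 15y8m-16y7m, i.e. about sixteen years."""
    a, b = parse_tap("86"), parse_tap("02.8")
    bounds = distance_bounds(a, b)
    assert (bounds.min_units, bounds.max_units) == (188, 199)
    assert bounds.unit is Unit.MONTHS
    assert bounds.min_units == 15 * 12 + 8
    assert bounds.max_units == 16 * 12 + 7
    assert distance_estimate(a, b) == 16


@pytest.mark.parametrize("raw_a, raw_b, expected", [
    ("86", "86", (0, 11, Unit.MONTHS)),
    ("1990", "2000", (109, 131, Unit.MONTHS)),
    ("02.8.1", "02.8.4", (3, 3, Unit.DAYS)),
])
def test_distance_bounds_examples(raw_a, raw_b, expected):
    bounds = distance_bounds(parse_tap(raw_a), parse_tap(raw_b))
    assert (bounds.min_units, bounds.max_units, bounds.unit) == expected


def test_distance_estimate_examples():
    assert distance_estimate(parse_tap("1990"), parse_tap("2000")) == 10
    same_day = parse_tap("02.8.4")
    assert distance_estimate(same_day, parse_tap("02.8.4")) == 0


def test_distance_requires_resolved_anchors():
    with pytest.raises(UnresolvedAnchorError, match="'b'"):
        distance_bounds(parse_tap("86"), parse_tap("postop"))
    with pytest.raises(UnresolvedAnchorError, match="'a'"):
        distance_bounds(parse_tap(""), parse_tap("86"))


# ---------------------------------------------------------------------------
# qualitative relation

@pytest.mark.parametrize("raw_a, raw_b, expected", [
    ("86", "02.8", Relation.BEFORE),
    ("02.8", "86", Relation.AFTER),
    ("from late 02.7", "02.8", Relation.BEFORE),
    ("02", "02.8", Relation.UNDETERMINED),       # containment
    ("postop", "02.8", Relation.UNDETERMINED),
    ("02.8", "02.8", Relation.SAME_EXPRESSION),
])
def test_qualitative_relation_examples(raw_a, raw_b, expected):
    assert qualitative_relation(parse_tap(raw_a), parse_tap(raw_b)) is expected


# ---------------------------------------------------------------------------
# randomized anchors vs the oracle

_random_anchor = st.one_of(
    st.integers(1940, 2025).map(lambda y: parse_tap(str(y))),
    st.tuples(st.integers(1940, 2025), st.integers(1, 12)).map(
        lambda ym: parse_tap(f"{ym[0]}.{ym[1]}")),
    st.tuples(st.integers(1940, 2025), st.integers(1, 12),
              st.integers(1, 28)).map(
        lambda ymd: parse_tap(f"{ymd[0]}.{ymd[1]}.{ymd[2]}")),
    st.tuples(st.integers(1, 12), st.sampled_from(["early", "mid", "late"]),
              st.integers(1940, 2025)).map(
        lambda t: parse_tap(f"{t[1]} {t[2]}.{t[0]}")),
)


@settings(derandomize=True, max_examples=500)
@given(_random_anchor, _random_anchor)
def test_bounds_match_endpoint_enumeration_oracle(a, b):
    bounds = distance_bounds(a, b)
    assert (bounds.min_units, bounds.max_units) == \
        oracle_bounds(a, b, bounds.unit)


@settings(derandomize=True, max_examples=500)
@given(_random_anchor, _random_anchor)
def test_relation_matches_oracle_and_antisymmetry(a, b):
    rel = qualitative_relation(a, b)
    if a.raw_text != b.raw_text:
        assert rel is oracle_relation(a, b)
    # anti-symmetry
    rev = qualitative_relation(b, a)
    if rel is Relation.BEFORE:
        assert rev is Relation.AFTER
    if rel is Relation.AFTER:
        assert rev is Relation.BEFORE


@settings(derandomize=True, max_examples=200)
@given(_random_anchor)
def test_zero_self_distance(anchor):
    assert distance_bounds(anchor, anchor).min_units == 0


@settings(derandomize=True, max_examples=200)
@given(st.integers(1950, 2020), st.integers(1, 12), _random_anchor)
def test_granularity_refinement_never_widens_bounds(year, month, other):
    """A month anchor inside a year anchor gives nested distance bounds."""
    coarse = parse_tap(str(year))
    fine = parse_tap(f"{year}.{month}")
    wide = distance_bounds(other, coarse)
    narrow = distance_bounds(other, fine)
    assert wide.unit == narrow.unit
    assert wide.min_units <= narrow.min_units
    assert narrow.max_units <= wide.max_units


# ---------------------------------------------------------------------------
# the problem-precedes-action axiom

def test_problem_precedes_action_axiom_and_membership():
    from vmodel.model import ClinicalEvent, VStructure

    sx = ClinicalEvent("e1", "dizziness", "Sx", 0, "02.8")
    test = ClinicalEvent("e2", "CT", "Test", 1, "02.8")
    v = VStructure("s1", parse_tap("02.8"), problems=[sx], actions=[test])
    assert problem_precedes_action(v, sx, test) is True
    stranger = ClinicalEvent("e3", "MRI", "Test", 2, "02.8")
    with pytest.raises(ValueError, match="not on the Problem wing"):
        problem_precedes_action(v, stranger, test)
    with pytest.raises(ValueError, match="not on the Action wing"):
        problem_precedes_action(v, sx, sx)
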