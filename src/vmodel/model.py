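"""Domain objects of the v-structure timeline model.

A patient's narrative history is modelled as an ordered sequence of
*v-structures*: each one anchors a temporal expression (TAP) at the base of
a "v" whose left wing holds the *Problems* (why — symptoms, purposes,
explicitly causal diagnoses/findings), whose right wing holds the *Actions*
(what was done), and to which administrative *Visit* items attach.

The semantic taxonomy is closed: exactly 14 tags, each permitted on fixed
wing positions.  Runs of consecutive, causally linked v-structures form
*context blocks*, the unit of pattern recognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Optional, Sequence

from .temporal import TemporalAnchor

__all__ = [
    "ClinicalEvent",
    "ContextBlock",
    "PatientTimeline",
    "Position",
    "SemanticType",
    "VStructure",
    "extract_context_blocks",
    "semantic_type",
    "taxonomy",
    "validate_event",
    "validate_structure",
    "validate_timeline",
]


class Position(str, Enum):
    """Wing position a semantic tag may occupy."""

    PROBLEM = "Problem"
    ACTION = "Action"
    VISIT = "Visit"


@dataclass(frozen=True)
class SemanticType:
    tag: str
    description: str
    allowed_positions: frozenset[Position]


def _st(tag: str, description: str, *positions: Position) -> SemanticType:
    return SemanticType(tag, description, frozenset(positions))


#: The closed 14-tag taxonomy, in canonical order.
_TAXONOMY: tuple[SemanticType, ...] = (
    _st("Purpose", "Purpose", Position.PROBLEM),
    _st("Sx", "Symptom", Position.PROBLEM),
    _st("Dx", "Diagnosis", Position.PROBLEM, Position.ACTION),
    _st("Finding", "Finding", Position.PROBLEM, Position.ACTION),
    _st("Drug", "Drug", Position.ACTION),
    _st("Op", "Operation", Position.ACTION),
    _st("Other", "Any other events", Position.ACTION),
    _st("Plan", "Plan", Position.ACTION),
    _st("Test", "Test", Position.ACTION),
    _st("Tx", "Treatment", Position.ACTION),
    _st("Adm", "Admission", Position.VISIT),
    _st("Death", "Death", Position.VISIT),
    _st("Disch", "Discharge", Position.VISIT),
    _st("Visit", "Hospital/Department visit information", Position.VISIT),
)

_BY_TAG = {t.tag: t for t in _TAXONOMY}


def taxonomy() -> list[SemanticType]:
    """All 14 semantic types, in canonical order."""
    return list(_TAXONOMY)


def semantic_type(tag: str) -> SemanticType:
    """Look up a tag; raises ``KeyError`` for tags outside the taxonomy."""
    try:
        return _BY_TAG[tag]
    except KeyError:
        raise KeyError(f"unknown semantic tag {tag!r}; "
                       f"valid tags: {', '.join(_BY_TAG)}") from None


@dataclass
class ClinicalEvent:
    """One annotated narrative event.

    ``causal_links`` holds the ids of events this event is a stated cause
    of (Problem -> Action direction: "due to cervix cancer, concurrent
    chemo RT was done" links the cancer event to the chemo event).
    ``raw_time`` is the verbatim temporal expression and is never
    normalised in storage.  Identity is the caller-supplied ``event_id``;
    two events with equal text (a CT test done twice) remain distinct.
    """

    event_id: str
    text: str
    semantic_type: str
    appearance_index: int
    raw_time: str = ""
    causal_links: set[str] = field(default_factory=set)


@dataclass
class VStructure:
    """One v-glyph: a TAP with Problem/Action wings and Visit items."""

    structure_id: str
    tap: TemporalAnchor
    problems: list[ClinicalEvent] = field(default_factory=list)
    actions: list[ClinicalEvent] = field(default_factory=list)
    visits: list[ClinicalEvent] = field(default_factory=list)
    #: True for a structure holding only administrative Visit items
    #: (an admission opening a record before any clinical event).
    visit_only: bool = False

    def events(self) -> list[ClinicalEvent]:
        return [*self.problems, *self.actions, *self.visits]


@dataclass
class PatientTimeline:
    """Ordered v-structures for one patient; the unit of rendering/mining.

    Ordering is chronological wherever TAP intervals decide it and
    narrative appearance order otherwise.  ``anchor_date`` (e.g. an
    admission or dictation date) resolves relative expressions.
    """

    patient_id: str
    structures: list[VStructure] = field(default_factory=list)
    anchor_date: Optional[date] = None


@dataclass
class ContextBlock:
    """A maximal run of consecutive, causally linked v-structures."""

    block_id: str
    structure_ids: tuple[str, ...]
    link_evidence: frozenset[tuple[str, str]] = frozenset()
    structures: tuple[VStructure, ...] = field(default=(), repr=False,
                                               compare=False)


# ---------------------------------------------------------------------------
# validation

def validate_event(event: ClinicalEvent) -> list[str]:
    """Check one event against the taxonomy and field invariants.

    Violations are returned (naming field and rule), never raised, so a
    whole document can be audited in one pass.
    """
    violations: list[str] = []
    if not event.event_id:
        violations.append("event_id: must be a nonempty identifier")
    if event.semantic_type not in _BY_TAG:
        violations.append(
            f"semantic_type: unknown semantic tag {event.semantic_type!r}")
    if event.appearance_index < 0:
        violations.append("appearance_index: must be non-negative")
    if event.event_id in event.causal_links:
        violations.append("causal_links: event may not cause itself")
    return violations


def validate_structure(v: VStructure) -> list[str]:
    """Check wing/position permissions and wing ordering of one structure."""
    violations: list[str] = []
    if not v.problems and not v.actions and not v.visit_only:
        violations.append(
            f"{v.structure_id}: problems and actions are both empty")
    for wing, position in ((v.problems, Position.PROBLEM),
                           (v.actions, Position.ACTION),
                           (v.visits, Position.VISIT)):
        for ev in wing:
            for issue in validate_event(ev):
                violations.append(f"{v.structure_id}/{ev.event_id}: {issue}")
            st = _BY_TAG.get(ev.semantic_type)
            if st is not None and position not in st.allowed_positions:
                violations.append(
                    f"{v.structure_id}/{ev.event_id}: semantic type "
                    f"{ev.semantic_type!r} may not occupy the "
                    f"{position.value} position")
        violations.extend(
            f"{v.structure_id}: {issue}"
            for issue in _check_wing_order(wing, position))
    return violations


def _check_wing_order(wing: Sequence[ClinicalEvent],
                      position: Position) -> list[str]:
    # events on a wing are grouped by semantic type; groups and the events
    # inside them follow appearance order (no order or gap is invented)
    issues: list[str] = []
    seen_groups: list[str] = []
    for prev, cur in zip(wing, wing[1:]):
        if (cur.semantic_type == prev.semantic_type
                and cur.appearance_index < prev.appearance_index):
            issues.append(
                f"{position.value} wing: events {prev.event_id!r}, "
                f"{cur.event_id!r} of type {cur.semantic_type!r} out of "
                "appearance order")
    for ev in wing:
        if not seen_groups or seen_groups[-1] != ev.semantic_type:
            if ev.semantic_type in seen_groups:
                issues.append(
                    f"{position.value} wing: semantic type "
                    f"{ev.semantic_type!r} split into non-adjacent groups")
            seen_groups.append(ev.semantic_type)
    return issues


def validate_timeline(timeline: PatientTimeline) -> list[str]:
    """Validate every structure plus cross-structure invariants."""
    violations: list[str] = []
    seen_indices: dict[int, str] = {}
    all_ids: set[str] = set()
    for v in timeline.structures:
        violations.extend(validate_structure(v))
        for ev in v.events():
            if ev.event_id in all_ids:
                violations.append(
                    f"{ev.event_id}: duplicate event_id in timeline")
            all_ids.add(ev.event_id)
            if ev.appearance_index in seen_indices and \
                    seen_indices[ev.appearance_index] != ev.event_id:
                violations.append(
                    f"{ev.event_id}: appearance_index "
                    f"{ev.appearance_index} duplicates "
                    f"{seen_indices[ev.appearance_index]!r}")
            seen_indices.setdefault(ev.appearance_index, ev.event_id)
    for v in timeline.structures:
        for ev in v.events():
            for target in ev.causal_links:
                if target not in all_ids:
                    violations.append(
                        f"{ev.event_id}: causal link to unknown event "
                        f"{target!r}")
    return violations


# ---------------------------------------------------------------------------
# context blocks

def _links_between(a: VStructure, b: VStructure) -> frozenset[tuple[str, str]]:
    ids_a = {ev.event_id for ev in a.events()}
    ids_b = {ev.event_id for ev in b.events()}
    links = set()
    for ev in a.events():
        links.update((ev.event_id, t) for t in ev.causal_links if t in ids_b)
    for ev in b.events():
        links.update((ev.event_id, t) for t in ev.causal_links if t in ids_a)
    return frozenset(links)


def _consecutive_linked(a: VStructure, b: VStructure) -> bool:
    if _links_between(a, b):
        return True
    # one temporal expression split into multiple v-structures (several
    # causal relationships under the same TAP) stays one context
    raw_a, raw_b = a.tap.raw_text.strip(), b.tap.raw_text.strip()
    return bool(raw_a) and raw_a == raw_b


def extract_context_blocks(timeline: PatientTimeline) -> list[ContextBlock]:
    """Partition the timeline into maximal runs of linked structures.

    Consecutive structures share a block iff a causal link crosses between
    them or they carry the same verbatim temporal expression; unlinked
    structures form singleton blocks.  Every structure lands in exactly one
    block and concatenating the blocks reproduces timeline order.
    """
    blocks: list[ContextBlock] = []
    run: list[VStructure] = []
    evidence: set[tuple[str, str]] = set()

    def flush() -> None:
        if run:
            blocks.append(ContextBlock(
                block_id=f"b{len(blocks) + 1}",
                structure_ids=tuple(v.structure_id for v in run),
                link_evidence=frozenset(evidence),
                structures=tuple(run)))

    for v in timeline.structures:
        if run and _consecutive_linked(run[-1], v):
            evidence.update(_links_between(run[-1], v))
            run.append(v)
        else:
            flush()
            run = [v]
            evidence = set()
    flush()
    return blocks
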