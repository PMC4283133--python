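"""Assembly of a flat annotated event list into a v-structure timeline.

The modelling strategy is deterministic:

* **Roles.**  Symptoms and purposes are always Problems.  Diagnoses and
  findings are Problems only when the text states them as a cause
  ("due to cervix cancer, concurrent chemo RT was done"); without an
  explicit causality expression the same event is an Action.  Drugs,
  operations, plans, tests, treatments and other events are Actions;
  admission/discharge/death/visit items are Visits.
* **Shared TAPs.**  Events carrying the same verbatim temporal expression
  share one temporal anchor.  Within such a group, each distinct causal
  relationship (a connected set of problems and the actions they link to)
  becomes its own v-structure; events without in-group links pool into a
  single residual structure.  A structure may populate only one wing.
* **Ordering.**  Structures follow the chronology of their anchors wherever
  the intervals decide it and narrative appearance order otherwise.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Iterable, Optional, Sequence

from .model import (ClinicalEvent, PatientTimeline, Position, VStructure,
                    semantic_type, validate_event)
from .temporal import (Dialect, Relation, TemporalAnchor, parse_tap,
                       qualitative_relation)
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyError",
    "RoleAssignment",
    "assign_role",
    "build_timeline",
    "link_problem_to_later_action",
]


class AssemblyError(ValueError):
    """Raised for inputs the modelling strategy cannot arrange."""


@dataclass(frozen=True)
class RoleAssignment:
    event_id: str
    role: Position
    rule_fired: str


_ALWAYS_PROBLEM = {"Purpose", "Sx"}
_CAUSALITY_DEPENDENT = {"Dx", "Finding"}
_ALWAYS_ACTION = {"Drug", "Op", "Other", "Plan", "Test", "Tx"}
_VISIT = {"Adm", "Death", "Disch", "Visit"}


def assign_role(event: ClinicalEvent,
                has_explicit_cause_link: bool) -> RoleAssignment:
    """Assign the wing role of one event.

    A pure function of (semantic tag, explicit-causality flag); diagnoses
    and findings flip between Problem and Action on that flag alone.
    """
    tag = event.semantic_type
    if tag in _ALWAYS_PROBLEM:
        return RoleAssignment(event.event_id, Position.PROBLEM,
                              "symptom/purpose is always a Problem")
    if tag in _CAUSALITY_DEPENDENT:
        if has_explicit_cause_link:
            return RoleAssignment(event.event_id, Position.PROBLEM,
                                  "explicitly stated cause")
        return RoleAssignment(event.event_id, Position.ACTION,
                              "diagnosis/finding without stated causality")
    if tag in _ALWAYS_ACTION:
        return RoleAssignment(event.event_id, Position.ACTION,
                              "clinical activity is an Action")
    if tag in _VISIT:
        return RoleAssignment(event.event_id, Position.VISIT,
                              "administrative information is a Visit")
    # raises the canonical taxonomy error
    semantic_type(tag)
    raise AssemblyError(f"unhandled tag {tag!r}")  # pragma: no cover


def _check_events(events: Sequence[ClinicalEvent]) -> None:
    ids = {}
    indices = {}
    for ev in events:
        problems = validate_event(ev)
        if problems:
            raise AssemblyError(
                f"invalid event {ev.event_id!r}: " + "; ".join(problems))
        if ev.event_id in ids:
            raise AssemblyError(f"duplicate event_id {ev.event_id!r}")
        ids[ev.event_id] = ev
        if ev.appearance_index in indices:
            raise AssemblyError(
                f"appearance_index {ev.appearance_index} shared by "
                f"{indices[ev.appearance_index]!r} and {ev.event_id!r}")
        indices[ev.appearance_index] = ev.event_id
    for ev in events:
        for target in ev.causal_links:
            if target not in ids:
                raise AssemblyError(
                    f"event {ev.event_id!r} links to {target!r}, which is "
                    "not an event of this patient")
    _check_acyclic(events)


def _check_acyclic(events: Sequence[ClinicalEvent]) -> None:
    graph = {ev.event_id: sorted(ev.causal_links) for ev in events}
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {k: WHITE for k in graph}
    stack: list[str] = []

    def visit(node: str) -> None:
        color[node] = GRAY
        stack.append(node)
        for nxt in graph[node]:
            if color[nxt] == GRAY:
                cycle = stack[stack.index(nxt):] + [nxt]
                raise AssemblyError(
                    "cyclic causal links: " + " -> ".join(cycle))
            if color[nxt] == WHITE:
                visit(nxt)
        stack.pop()
        color[node] = BLACK

    for node in sorted(graph):
        if color[node] == WHITE:
            visit(node)


def _components(problems: list[ClinicalEvent], actions: list[ClinicalEvent]
                ) -> list[tuple[list[ClinicalEvent], list[ClinicalEvent]]]:
    """Connected components of the in-group problem->action link graph.

    Each component is one distinct causal relationship and becomes one
    v-structure; two problems sharing an action therefore merge rather
    than duplicating the action across structures.
    """
    action_ids = {ev.event_id: ev for ev in actions}
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    linked_problems = []
    for p in problems:
        targets = [t for t in p.causal_links if t in action_ids]
        if not targets:
            continue
        linked_problems.append(p)
        parent.setdefault(p.event_id, p.event_id)
        for t in targets:
            parent.setdefault(t, t)
            union(p.event_id, t)

    groups: dict[str, tuple[list[ClinicalEvent], list[ClinicalEvent]]] = {}
    for p in linked_problems:
        groups.setdefault(find(p.event_id), ([], []))[0].append(p)
    for a in actions:
        if a.event_id in parent:
            groups.setdefault(find(a.event_id), ([], []))[1].append(a)
    ordered = sorted(
        groups.values(),
        key=lambda pa: min(ev.appearance_index for ev in pa[0] + pa[1]))
    return ordered


def _sort_wing(wing: list[ClinicalEvent]) -> list[ClinicalEvent]:
    # groups by semantic type in order of each type's first appearance,
    # events inside a group in appearance order
    by_appearance = sorted(wing, key=lambda ev: ev.appearance_index)
    first_seen: dict[str, int] = {}
    for ev in by_appearance:
        first_seen.setdefault(ev.semantic_type, ev.appearance_index)
    return sorted(by_appearance,
                  key=lambda ev: (first_seen[ev.semantic_type],
                                  ev.appearance_index))


def build_timeline(events: Iterable[ClinicalEvent],
                   anchor_date: Optional[date] = None,
                   patient_id: str = "patient",
                   dialect: Dialect | None = None) -> PatientTimeline:
    """Arrange one patient's events into an ordered v-structure timeline.

    Events with an empty ``raw_time`` inherit the nearest preceding
    temporal expression (narration stays in order when time is omitted).
    Raises :class:`AssemblyError` on duplicate ids/indices, dangling or
    cyclic causal links.
    """
    event_list = sorted(events, key=lambda ev: ev.appearance_index)
    _check_events(event_list)
    timeline = PatientTimeline(patient_id=patient_id, structures=[],
                               anchor_date=anchor_date)
    if not event_list:
        return timeline

    # group by effective verbatim expression, preserving first appearance
    groups: dict[str, list[ClinicalEvent]] = {}
    group_order: list[str] = []
    current_raw = ""
    for ev in event_list:
        raw = ev.raw_time.strip()
        if raw:
            current_raw = raw
        key = current_raw
        if key not in groups:
            groups[key] = []
            group_order.append(key)
        groups[key].append(ev)

    taps = {raw: parse_tap(raw, anchor_date, dialect) for raw in group_order}

    structures: list[VStructure] = []
    pending_visits: list[ClinicalEvent] = []
    for raw in group_order:
        members = groups[raw]
        tap = taps[raw]
        roles = {ev.event_id: assign_role(ev, bool(ev.causal_links))
                 for ev in members}
        problems = [ev for ev in members
                    if roles[ev.event_id].role is Position.PROBLEM]
        actions = [ev for ev in members
                   if roles[ev.event_id].role is Position.ACTION]
        visits = [ev for ev in members
                  if roles[ev.event_id].role is Position.VISIT]

        group_structures: list[VStructure] = []
        claimed: set[str] = set()
        for comp_problems, comp_actions in _components(problems, actions):
            claimed.update(ev.event_id for ev in comp_problems + comp_actions)
            group_structures.append(VStructure(
                structure_id="", tap=tap,
                problems=_sort_wing(comp_problems),
                actions=_sort_wing(comp_actions)))
        residual_p = [ev for ev in problems if ev.event_id not in claimed]
        residual_a = [ev for ev in actions if ev.event_id not in claimed]
        if residual_p or residual_a:
            group_structures.append(VStructure(
                structure_id="", tap=tap,
                problems=_sort_wing(residual_p),
                actions=_sort_wing(residual_a)))

        if group_structures:
            # visits attach to the first structure that shares their TAP,
            # absorbing any carried over from visit-only groups before it
            group_structures[0].visits = _sort_wing(
                pending_visits + visits)
            pending_visits = []
            structures.extend(group_structures)
        else:
            pending_visits.extend(visits)

    if pending_visits:
        # no following clinical structure exists: a Visit-only structure
        raw = pending_visits[0].raw_time.strip()
        structures.append(VStructure(
            structure_id="", tap=parse_tap(raw, anchor_date, dialect),
            visits=_sort_wing(pending_visits), visit_only=True))

    _chronological_sort(structures)
    for i, v in enumerate(structures, start=1):
        v.structure_id = f"s{i}"
    timeline.structures = structures
    return timeline


def _min_appearance(v: VStructure) -> int:
    return min(ev.appearance_index for ev in v.events())


def _chronological_sort(structures: list[VStructure]) -> None:
    """Insertion sort under a partial order.

    Resolvable anchor pairs compare chronologically; all other pairs keep
    appearance order.  A structure narrated out of chronological order is
    moved, with a warning — the timeline is the product.
    """
    structures.sort(key=_min_appearance)
    for i in range(1, len(structures)):
        j = i
        while j > 0:
            rel = qualitative_relation(structures[j].tap,
                                       structures[j - 1].tap)
            if rel is Relation.BEFORE:
                logger.warning(
                    "structure anchored at %r narrated after %r but "
                    "chronologically earlier; reordering",
                    structures[j].tap.raw_text,
                    structures[j - 1].tap.raw_text)
                structures[j], structures[j - 1] = (structures[j - 1],
                                                    structures[j])
                j -= 1
            else:
                break


def link_problem_to_later_action(timeline: PatientTimeline,
                                 problem_event_id: str,
                                 action_event_id: str) -> PatientTimeline:
    """Record a causal link from a problem to a temporally separate action.

    Chief complaints starting in late July may explain tests done in
    August; the link joins the two structures into one context and renders
    as a facing wing pair.  The action's structure must not precede the
    problem's.
    """
    if problem_event_id == action_event_id:
        raise AssemblyError("an event cannot cause itself")
    p_idx = a_idx = None
    p_event = None
    for idx, v in enumerate(timeline.structures):
        for ev in v.problems:
            if ev.event_id == problem_event_id:
                p_idx, p_event = idx, ev
        for ev in v.actions:
            if ev.event_id == action_event_id:
                a_idx = idx
    if p_event is None:
        raise AssemblyError(
            f"no problem event {problem_event_id!r} in timeline")
    if a_idx is None:
        raise AssemblyError(
            f"no action event {action_event_id!r} in timeline")
    if a_idx < p_idx:
        raise AssemblyError(
            f"action {action_event_id!r} precedes its problem "
            f"{problem_event_id!r}: a cause cannot follow its effect")
    p_event.causal_links.add(action_event_id)
    return timeline
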