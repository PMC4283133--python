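"""Deterministic layout and SVG rendering of v-structure timelines.

The layout realises the dynamic-scale principle: successive temporal
anchors sit at *equal* horizontal spacing regardless of the elapsed time
between them, so a sixteen-year gap and a one-day gap occupy the same
width and coarse past history coexists with minute-level emergencies in a
single view.  Problem wings extend up-left (red), Action wings up-right
(blue); semantic tag boxes precede each run of same-tagged events; Visit
items sit in a strip below the baseline; cross-structure causal links draw
as arcs under the baseline; TAP labels show the verbatim expression, never
a normalised date.

Rendering is pure: identical timeline + config give byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional
from xml.sax.saxutils import escape

from .model import PatientTimeline, VStructure, extract_context_blocks

__all__ = [
    "LayoutGeometry",
    "RenderConfig",
    "layout",
    "render_svg",
    "render_timeline",
    "render_tap_labels",
]


@dataclass(frozen=True)
class RenderConfig:
    """Tunable geometry and style; defaults are aesthetic choices.

    ``unit_spacing`` is the constant pixel distance between consecutive
    TAP marks (the dynamic scale); ``wing_angle`` the wing slope from the
    baseline in degrees.
    """

    unit_spacing: float = 170.0
    wing_angle: float = 55.0
    problem_color: str = "#CC0000"
    action_color: str = "#0033CC"
    visit_color: str = "#444444"
    font_size: float = 11.0
    char_width: float = 6.3
    label_height: float = 15.0
    label_gap: float = 4.0
    wing_base: float = 22.0
    tag_box_size: float = 12.0
    margin: float = 42.0
    visit_row_height: float = 18.0
    show_context_blocks: bool = False

    def __post_init__(self) -> None:
        if self.unit_spacing <= 0:
            raise ValueError("unit_spacing must be positive")
        if not 15.0 <= self.wing_angle <= 75.0:
            raise ValueError("wing_angle must lie in [15, 75] degrees")


@dataclass(frozen=True)
class Box:
    x: float
    y: float
    width: float
    height: float

    def intersects(self, other: "Box") -> bool:
        return (self.x < other.x + other.width
                and other.x < self.x + self.width
                and self.y < other.y + other.height
                and other.y < self.y + self.height)


@dataclass
class LabelBox:
    structure_id: str
    side: str                     # "problem" | "action"
    text: str
    box: Box
    is_tag: bool = False
    color: Optional[str] = None   # tag boxes carry the wing colour


@dataclass
class WingLine:
    structure_id: str
    side: str
    x1: float
    y1: float
    x2: float
    y2: float


@dataclass
class TapMark:
    structure_id: str
    x: float
    label: str                    # verbatim raw_time; "" when shared/missing
    label_x: float                # centre of the (possibly shared) label


@dataclass
class LinkArc:
    source_structure: str
    target_structure: str
    x1: float
    x2: float
    y: float


@dataclass
class LayoutGeometry:
    width: float
    height: float
    baseline_y: float
    tap_marks: list[TapMark] = field(default_factory=list)
    wings: list[WingLine] = field(default_factory=list)
    labels: list[LabelBox] = field(default_factory=list)
    visit_labels: list[LabelBox] = field(default_factory=list)
    links: list[LinkArc] = field(default_factory=list)
    block_rects: list[Box] = field(default_factory=list)


def render_tap_labels(timeline: PatientTimeline) -> list[str]:
    """Per-structure TAP label strings — always the verbatim expression."""
    return [v.tap.raw_text for v in timeline.structures]


def _wing_items(v: VStructure, side: str) -> list[tuple[bool, str, str]]:
    """(is_tag, tag, text) items along a wing, tag box ahead of each run."""
    events = v.problems if side == "problem" else v.actions
    items: list[tuple[bool, str, str]] = []
    last_tag = None
    for ev in events:
        if ev.semantic_type != last_tag:
            items.append((True, ev.semantic_type, ev.semantic_type))
            last_tag = ev.semantic_type
        items.append((False, ev.semantic_type, ev.text))
    return items


def layout(timeline: PatientTimeline, config: RenderConfig | None = None
           ) -> LayoutGeometry:
    """Compute deterministic coordinates for a timeline.

    TAP marks are strictly increasing in x with equal gaps; wing labels
    stack upward along the wing with overlaps resolved by deterministic
    upward nudges; canvas height follows the deepest wing, not the number
    of distinct event concepts.
    """
    config = config or RenderConfig()
    n = len(timeline.structures)
    structures = timeline.structures

    slot_pitch = config.label_height + config.label_gap
    max_items = 0
    max_visits = 0
    for v in structures:
        max_items = max(max_items,
                        len(_wing_items(v, "problem")),
                        len(_wing_items(v, "action")))
        max_visits = max(max_visits, len(v.visits) + (1 if v.visits else 0))
    wing_height = config.wing_base + max_items * slot_pitch
    baseline_y = config.margin + wing_height + config.label_height
    height = (baseline_y + config.label_height + config.label_gap
              + max_visits * config.visit_row_height + config.margin)
    width = 2 * config.margin + max(n - 1, 0) * config.unit_spacing
    geometry = LayoutGeometry(width=width, height=height,
                              baseline_y=baseline_y)
    if n == 0:
        return geometry

    tan = math.tan(math.radians(config.wing_angle))
    xs = [config.margin + i * config.unit_spacing for i in range(n)]

    # shared-expression runs get a single centred TAP label
    i = 0
    label_centres: dict[int, tuple[str, float]] = {}
    while i < n:
        j = i
        raw = structures[i].tap.raw_text.strip()
        while (j + 1 < n and raw
               and structures[j + 1].tap.raw_text.strip() == raw):
            j += 1
        label_centres[i] = (structures[i].tap.raw_text,
                            (xs[i] + xs[j]) / 2.0)
        i = j + 1

    for idx, v in enumerate(structures):
        label, centre = label_centres.get(idx, ("", xs[idx]))
        geometry.tap_marks.append(
            TapMark(v.structure_id, xs[idx], label, centre))

    placed: list[Box] = []
    for idx, v in enumerate(structures):
        x0 = xs[idx]
        for side, direction in (("problem", -1), ("action", +1)):
            items = _wing_items(v, side)
            if items:
                top_dy = config.wing_base + len(items) * slot_pitch
                geometry.wings.append(WingLine(
                    v.structure_id, side,
                    x0, baseline_y,
                    x0 + direction * top_dy / tan, baseline_y - top_dy))
            for slot, (is_tag, tag, text) in enumerate(items):
                dy = config.wing_base + (slot + 1) * slot_pitch
                px = x0 + direction * dy / tan
                py = baseline_y - dy
                if is_tag:
                    w = config.tag_box_size + len(text) * config.char_width
                    h = config.label_height
                else:
                    w = len(text) * config.char_width + 6.0
                    h = config.label_height
                bx = px if direction > 0 else px - w
                box = Box(bx, py - h, w, h)
                box = _nudge(box, placed)
                placed.append(box)
                geometry.labels.append(LabelBox(
                    v.structure_id, side, text, box, is_tag,
                    (config.problem_color if side == "problem"
                     else config.action_color) if is_tag else None))
        for row, ev in enumerate(v.visits):
            w = len(ev.text) * config.char_width + 6.0
            y = (baseline_y + config.label_height + config.label_gap
                 + (row + 1) * config.visit_row_height)
            geometry.visit_labels.append(LabelBox(
                v.structure_id, "visit", ev.text,
                Box(x0 - w / 2.0, y - config.label_height, w,
                    config.label_height)))

    # cross-structure problem->action causal links as under-baseline arcs
    action_home = {ev.event_id: idx
                   for idx, v in enumerate(structures) for ev in v.actions}
    for idx, v in enumerate(structures):
        for ev in v.problems:
            for target in sorted(ev.causal_links):
                t_idx = action_home.get(target)
                if t_idx is not None and t_idx != idx:
                    geometry.links.append(LinkArc(
                        v.structure_id, structures[t_idx].structure_id,
                        xs[idx], xs[t_idx], baseline_y))

    if config.show_context_blocks:
        index_of = {v.structure_id: i for i, v in enumerate(structures)}
        pad = config.unit_spacing * 0.35
        for block in extract_context_blocks(timeline):
            first = index_of[block.structure_ids[0]]
            last = index_of[block.structure_ids[-1]]
            geometry.block_rects.append(Box(
                xs[first] - pad, config.margin / 2.0,
                xs[last] - xs[first] + 2 * pad,
                height - config.margin))
    return geometry


def _nudge(box: Box, placed: list[Box]) -> Box:
    """Move a box upward until it clears all previously placed boxes."""
    moved = True
    guard = 0
    while moved and guard < 10_000:
        moved = False
        for other in placed:
            if box.intersects(other):
                box = Box(box.x, other.y - box.height - 2.0,
                          box.width, box.height)
                moved = True
        guard += 1
    return box


def _f(value: float) -> str:
    return f"{value:.2f}"


def render_svg(geometry: LayoutGeometry,
               config: RenderConfig | None = None) -> str:
    """Serialise a layout to an SVG 1.1 document (string).

    Pure string assembly with fixed numeric formatting, so identical
    inputs produce byte-identical output.
    """
    config = config or RenderConfig()
    out: list[str] = []
    # translate everything so no coordinate is negative (labels may have
    # been nudged above the canvas top)
    min_y = 0.0
    for label in geometry.labels:
        min_y = min(min_y, label.box.y)
    shift = -min_y + (4.0 if min_y < 0 else 0.0)
    height = geometry.height + shift

    def y(v: float) -> str:
        return _f(v + shift)

    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(geometry.width)}" height="{_f(height)}" '
        f'viewBox="0 0 {_f(geometry.width)} {_f(height)}">')
    out.append(f'<rect class="canvas" x="0" y="0" '
               f'width="{_f(geometry.width)}" height="{_f(height)}" '
               f'fill="#FFFFFF"/>')

    for box in geometry.block_rects:
        out.append(
            f'<rect class="context-block" x="{_f(box.x)}" y="{y(box.y)}" '
            f'width="{_f(box.width)}" height="{_f(box.height)}" '
            f'fill="#DDDDDD" fill-opacity="0.5" stroke="none"/>')

    out.append(
        f'<line class="baseline" x1="0" y1="{y(geometry.baseline_y)}" '
        f'x2="{_f(geometry.width)}" y2="{y(geometry.baseline_y)}" '
        f'stroke="#000000" stroke-width="1.2"/>')

    for arc in geometry.links:
        mid = (arc.x1 + arc.x2) / 2.0
        depth = min(40.0, abs(arc.x2 - arc.x1) * 0.25)
        out.append(
            f'<path class="link" d="M {_f(arc.x1)} {y(arc.y)} '
            f'Q {_f(mid)} {y(arc.y + depth)} {_f(arc.x2)} {y(arc.y)}" '
            f'fill="none" stroke="#888888" stroke-width="1.0" '
            f'stroke-dasharray="4 3"/>')

    for wing in geometry.wings:
        color = (config.problem_color if wing.side == "problem"
                 else config.action_color)
        out.append(
            f'<path class="wing wing-{wing.side}" '
            f'd="M {_f(wing.x1)} {y(wing.y1)} L {_f(wing.x2)} {y(wing.y2)}" '
            f'fill="none" stroke="{color}" stroke-width="1.6"/>')

    for mark in geometry.tap_marks:
        out.append(
            f'<line class="tap-mark" x1="{_f(mark.x)}" '
            f'y1="{y(geometry.baseline_y - 5)}" x2="{_f(mark.x)}" '
            f'y2="{y(geometry.baseline_y + 5)}" '
            f'stroke="#000000" stroke-width="1.4"/>')
        if mark.label:
            out.append(
                f'<text class="tap-label" x="{_f(mark.label_x)}" '
                f'y="{y(geometry.baseline_y + 16)}" '
                f'text-anchor="middle" font-size="{_f(config.font_size)}" '
                f'font-family="sans-serif">{escape(mark.label)}</text>')

    for label in geometry.labels:
        if label.is_tag:
            out.append(
                f'<rect class="tag-box" x="{_f(label.box.x)}" '
                f'y="{y(label.box.y)}" '
                f'width="{_f(config.tag_box_size)}" '
                f'height="{_f(config.tag_box_size)}" '
                f'fill="{label.color}"/>')
            out.append(
                f'<text class="tag-label" '
                f'x="{_f(label.box.x + config.tag_box_size + 3)}" '
                f'y="{y(label.box.y + label.box.height - 4)}" '
                f'font-size="{_f(config.font_size)}" '
                f'font-family="sans-serif" font-weight="bold">'
                f'{escape(label.text)}</text>')
        else:
            out.append(
                f'<text class="event-label" x="{_f(label.box.x + 3)}" '
                f'y="{y(label.box.y + label.box.height - 4)}" '
                f'font-size="{_f(config.font_size)}" '
                f'font-family="sans-serif">{escape(label.text)}</text>')

    for label in geometry.visit_labels:
        out.append(
            f'<text class="visit-label" x="{_f(label.box.x + 3)}" '
            f'y="{y(label.box.y + label.box.height - 4)}" '
            f'font-size="{_f(config.font_size)}" '
            f'font-family="sans-serif" fill="{config.visit_color}">'
            f'{escape(label.text)}</text>')

    out.append('</svg>')
    return "\n".join(out) + "\n"


def render_timeline(timeline: PatientTimeline,
                    config: RenderConfig | None = None) -> str:
    """Layout + SVG in one call."""
    config = config or RenderConfig()
    return render_svg(layout(timeline, config), config)
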