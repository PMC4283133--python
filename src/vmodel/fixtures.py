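"""Synthetic cohorts and worked-example timelines.

Nothing in this package touches clinical data: every test input is
generated here.  :func:`generate_cohort` builds seeded target/background
cohorts of v-structure timelines with *planted* block patterns at a
controlled support, noise blocks drawn from per-patient signature pools,
and temporal expressions sampled across the dialect's granularities
(year/month/day, fuzzy, relative, proximity hints).
:func:`fig5_scenario` instantiates the include/exclude mining scenario: a
red→green block bigram (pattern A) in every target patient, and in every
background patient the same bigram preceded by a red→blue bigram
(pattern B).  :func:`figure3_fixture` is a synthetic reconstruction of the
worked gastric-cancer example ('86 operation, complaints from late 02.7,
August 2002 work-up, postop treatment).

Event texts are template strings ("Sx_3"), never realistic PHI-like
content.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

from .assembler import build_timeline, link_problem_to_later_action
from .model import ClinicalEvent, PatientTimeline
from .patterns import BlockSignature, PatternSignature, SignatureMode

__all__ = [
    "CohortSpec",
    "PlantedPattern",
    "fig5_scenario",
    "figure3_fixture",
    "generate_cohort",
    "generate_cohort_events",
    "PATTERN_A",
    "PATTERN_B",
]

#: red block: a symptom answered by a test
_RED: BlockSignature = ((("Sx",), ("Test",)),)
#: green block: a symptom answered by a drug
_GREEN: BlockSignature = ((("Sx",), ("Drug",)),)
#: blue block: a symptom answered by an operation
_BLUE: BlockSignature = ((("Sx",), ("Op",)),)

#: the cohort-defining bigram: red block directly followed by green
PATTERN_A = PatternSignature((_RED, _GREEN), SignatureMode.SEMANTIC_TYPE)
#: the confounder bigram: red block directly followed by blue
PATTERN_B = PatternSignature((_RED, _BLUE), SignatureMode.SEMANTIC_TYPE)


@dataclass(frozen=True)
class PlantedPattern:
    """A signature planted into ``support`` of one group's timelines."""

    signature: PatternSignature
    support: float
    group: str                                   # "target" | "background"
    #: Fig 5(b): insert this immediately before the planted pattern
    confounder_before: Optional[PatternSignature] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must lie in [0, 1]")
        if self.group not in ("target", "background"):
            raise ValueError("group must be 'target' or 'background'")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_target: int = 5
    n_background: int = 5
    planted_patterns: tuple[PlantedPattern, ...] = ()
    blocks_per_timeline: tuple[int, int] = (3, 6)
    #: sampling weights over temporal expression forms for noise blocks
    tap_granularity_mix: dict[str, float] = field(default_factory=lambda: {
        "year": 0.2, "month": 0.35, "day": 0.25, "relative": 0.1,
        "hint": 0.1, "missing": 0.0})
    #: fraction of each timeline's block budget filled with noise blocks
    noise_block_rate: float = 1.0
    seed: int = 0


_HINT_PHRASES = ("postop", "preop", "at follow-up", "after chemo",
                 "on transfer", "post discharge")

_NOISE_PROBLEM_TAGS = ("Sx", "Purpose")
_NOISE_ACTION_TAGS = ("Test", "Drug", "Op", "Tx", "Plan", "Other")


def _noise_pool(exclude: set[BlockSignature]) -> list[BlockSignature]:
    pool: list[BlockSignature] = []
    action_sets = [
        (a,) for a in _NOISE_ACTION_TAGS
    ] + [tuple(sorted(pair))
         for pair in itertools.combinations(_NOISE_ACTION_TAGS, 2)]
    for p in _NOISE_PROBLEM_TAGS:
        for acts in action_sets:
            sig: BlockSignature = (((p,), acts),)
            if sig not in exclude:
                pool.append(sig)
    return pool


class _PatientBuilder:
    """Accumulates events for one synthetic patient along a date cursor."""

    def __init__(self, patient_id: str, rng: random.Random,
                 anchor_date: date) -> None:
        self.patient_id = patient_id
        self.rng = rng
        self.anchor_date = anchor_date
        self.events: list[ClinicalEvent] = []
        self.cursor = date(1960 + rng.randrange(20), 1 + rng.randrange(12),
                           1 + rng.randrange(28))
        self.used_raws: set[str] = set()
        self.hints = list(_HINT_PHRASES)
        rng.shuffle(self.hints)
        self._counter = 0

    def _next_id(self, prefix: str) -> str:
        self._counter += 1
        return f"{self.patient_id}-{prefix}{self._counter}"

    def _advance(self) -> None:
        months = 1 + self.rng.randrange(18)
        y, m = divmod(self.cursor.year * 12 + self.cursor.month - 1 + months,
                      12)
        self.cursor = date(y, m + 1, 1 + self.rng.randrange(28))

    def _raw_time(self, form: str) -> str:
        for _ in range(40):
            raw = self._format_raw(form)
            if raw not in self.used_raws:
                self.used_raws.add(raw)
                return raw
            self._advance()
        raw = self._format_raw("day")
        self.used_raws.add(raw)
        return raw

    def _format_raw(self, form: str) -> str:
        c = self.cursor
        yy = f"{c.year % 100:02d}"
        if form == "year":
            return yy if self.rng.random() < 0.5 else f"{c.year}"
        if form == "month":
            raw = f"{yy}.{c.month}"
            roll = self.rng.random()
            if roll < 0.15:
                return f"late {raw}"
            if roll < 0.25:
                return f"from early {raw}"
            return raw
        if form == "day":
            return f"{yy}.{c.month}.{c.day}"
        if form == "relative":
            days = (self.anchor_date - c).days
            if days <= 0:
                return f"{yy}.{c.month}.{c.day}"
            return f"{days} days ago"
        if form == "hint":
            if self.hints:
                return self.hints.pop()
            return f"at visit {self._counter}"
        return f"{yy}.{c.month}.{c.day}"

    def add_block(self, signature: BlockSignature, form: str,
                  extra_missing: int = 0) -> None:
        """Append one context block realising ``signature``.

        Every structure of a multi-structure block needs both wings (the
        problem→action links are what keep the structures distinct under a
        shared expression); a single-structure block may be one-winged.
        """
        self._advance()
        raw = self._raw_time(form)
        residuals = sum(1 for p, a in signature if not p or not a)
        if len(signature) > 1 and residuals > 1:
            raise ValueError(
                "infeasible block signature: at most one structure of a "
                "shared-expression block may lack problem-action links")
        for problems, actions in signature:
            action_ids = []
            for tag in actions:
                ev = ClinicalEvent(self._next_id("a"), f"{tag}_ev",
                                   tag, len(self.events), raw)
                action_ids.append(ev.event_id)
                self.events.append(ev)
            for tag in problems:
                self.events.append(ClinicalEvent(
                    self._next_id("p"), f"{tag}_ev", tag,
                    len(self.events), raw,
                    causal_links=set(action_ids)))
        for _ in range(extra_missing):
            tag = self.rng.choice(_NOISE_ACTION_TAGS)
            self.events.append(ClinicalEvent(
                self._next_id("m"), f"{tag}_ev", tag, len(self.events), ""))


def _plan_counts(support: float, n: int) -> int:
    return min(n, math.ceil(support * n))


def generate_cohort_events(
        spec: CohortSpec
) -> tuple[list[tuple[str, date, list[ClinicalEvent]]],
           list[tuple[str, date, list[ClinicalEvent]]]]:
    """Seeded event tables for both groups: (patient_id, anchor, events)."""
    rng = random.Random(spec.seed)
    lo, hi = spec.blocks_per_timeline
    if not (1 <= lo <= hi):
        raise ValueError("blocks_per_timeline must be a nonempty range")
    planted_sigs: set[BlockSignature] = set()
    for planted in spec.planted_patterns:
        planted_sigs.update(planted.signature.blocks)
        if planted.confounder_before is not None:
            planted_sigs.update(planted.confounder_before.blocks)
        span = len(planted.signature.blocks) + (
            len(planted.confounder_before.blocks)
            if planted.confounder_before else 0)
        if span > hi:
            raise ValueError(
                f"infeasible spec: planted pattern spans {span} blocks but "
                f"blocks_per_timeline allows at most {hi}")
    pool = _noise_pool(planted_sigs)
    forms = [f for f, w in spec.tap_granularity_mix.items() if w > 0]
    weights = [spec.tap_granularity_mix[f] for f in forms]
    missing_rate = spec.tap_granularity_mix.get("missing", 0.0)

    groups: dict[str, list[tuple[str, date, list[ClinicalEvent]]]] = {
        "target": [], "background": []}
    total = spec.n_target + spec.n_background
    patient_no = 0
    for group, count in (("target", spec.n_target),
                         ("background", spec.n_background)):
        plans: dict[int, list[PlantedPattern]] = {i: [] for i in range(count)}
        for planted in spec.planted_patterns:
            if planted.group != group:
                continue
            for i in sorted(rng.sample(range(count),
                                       _plan_counts(planted.support, count))):
                plans[i].append(planted)
        for i in range(count):
            pid = f"{'T' if group == 'target' else 'B'}{i + 1:03d}"
            # per-patient noise pool slice: cross-patient noise collisions
            # cannot fake a cohort-wide pattern
            my_pool = pool[patient_no::total] or pool
            anchor = date(2005, 6, 15)
            builder = _PatientBuilder(pid, random.Random(
                rng.randrange(2**31)), anchor)
            budget = lo + builder.rng.randrange(hi - lo + 1)
            n_noise = round(budget * spec.noise_block_rate)
            planted_here = plans[i]
            slots = n_noise
            insert_at = {p: builder.rng.randrange(slots + 1)
                         for p in planted_here} if planted_here else {}
            for slot in range(slots + 1):
                for planted in planted_here:
                    if insert_at.get(planted) == slot:
                        if planted.confounder_before is not None:
                            for sig in planted.confounder_before.blocks:
                                builder.add_block(sig, "month")
                        for sig in planted.signature.blocks:
                            builder.add_block(sig, "month")
                if slot < slots:
                    noise_sig = builder.rng.choice(my_pool)
                    form = builder.rng.choices(forms, weights)[0]
                    extra = (1 if builder.rng.random() < missing_rate else 0)
                    builder.add_block(noise_sig, form, extra_missing=extra)
            groups[group].append((pid, anchor, builder.events))
            patient_no += 1
    return groups["target"], groups["background"]


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[PatientTimeline], list[PatientTimeline]]:
    """Seeded, reproducible (target, background) timeline cohorts."""
    target_events, background_events = generate_cohort_events(spec)
    return ([build_timeline(events, anchor, pid)
             for pid, anchor, events in target_events],
            [build_timeline(events, anchor, pid)
             for pid, anchor, events in background_events])


def fig5_scenario(seed: int = 0, n_target: int = 5, n_background: int = 5,
                  noise_block_rate: float = 1.0) -> CohortSpec:
    """The include/exclude mining scenario.

    Every target patient carries pattern A (red→green); every background
    patient carries pattern A immediately preceded by pattern B
    (red→blue).  A sound miner must induce: include A, exclude A
    following B.
    """
    return CohortSpec(
        n_target=n_target,
        n_background=n_background,
        planted_patterns=(
            PlantedPattern(PATTERN_A, 1.0, "target"),
            PlantedPattern(PATTERN_A, 1.0, "background",
                           confounder_before=PATTERN_B),
        ),
        blocks_per_timeline=(4, 7),
        noise_block_rate=noise_block_rate,
        seed=seed,
    )


def figure3_fixture() -> PatientTimeline:
    """Synthetic reconstruction of the worked gastric-cancer example.

    A 1986 total-gastrectomy operation ('86), chief complaints from late
    July 2002 causally linked to the August 2002 work-up (Br. MRI, r/o CRP
    diagnosis, NTR of tm.), and postoperative FAM chemotherapy anchored
    only by the proximity hint "postop".
    """
    events = [
        ClinicalEvent("op-1986", "TG c Roux-en-Y anastomosis", "Op", 0,
                      "86"),
        ClinicalEvent("cc-0207", "chief complaints", "Sx", 1,
                      "from late 02.7", causal_links={"mri-0208"}),
        ClinicalEvent("mri-0208", "Br. MRI", "Test", 2, "02.8"),
        ClinicalEvent("dx-0208", "r/o CRP diagnosis", "Dx", 3, "02.8"),
        ClinicalEvent("op-0208", "NTR of tm.", "Op", 4, "02.8"),
        ClinicalEvent("tx-postop", "FAM", "Tx", 5, "postop"),
    ]
    return build_timeline(events, patient_id="fig3-synthetic")
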