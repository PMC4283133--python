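"""Context-block signatures and include/exclude phenotype rule mining.

A patient timeline reduces to a sequence of context-block *signatures*;
a candidate phenotype pattern is a contiguous n-gram of such signatures.
If a pattern recurs across a target cohort it is a candidate inclusion
criterion; if background (non-target) patients show the same pattern but
only ever preceded by another frequent pattern, that preceding pattern
becomes an exclusion clause — "include pattern A, exclude A following B".
Rules can additionally carry a temporal window on the include match
relative to the patient's first anchor (e.g. early childhood).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .model import ContextBlock, PatientTimeline, extract_context_blocks
from .temporal import (DurationBounds, TemporalAnchor, distance_bounds)

__all__ = [
    "BlockSignature",
    "MiningResult",
    "PatternSignature",
    "PhenotypeRule",
    "SignatureMode",
    "block_signature",
    "evaluate_rule",
    "find_matches",
    "mine_rules",
    "signature_sequence",
]


class SignatureMode(str, Enum):
    """Abstraction level at which blocks compare equal."""

    SEMANTIC_TYPE = "semantic_type"   # wings as multisets of semantic tags
    CONCEPT_LABEL = "concept_label"   # wings as multisets of event texts


#: per-structure wing multisets: ((problems...), (actions...)), sorted
StructureSignature = tuple[tuple[str, ...], tuple[str, ...]]
#: one context block: its structures' signatures in order
BlockSignature = tuple[StructureSignature, ...]


@dataclass(frozen=True)
class PatternSignature:
    """An ordered run of context-block signatures, with its mode."""

    blocks: tuple[BlockSignature, ...]
    mode: SignatureMode = SignatureMode.SEMANTIC_TYPE

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a pattern signature must contain >= 1 block")

    def __len__(self) -> int:
        return len(self.blocks)

    def serialize(self) -> str:
        return json.dumps({"mode": self.mode.value,
                           "blocks": self.blocks}, separators=(",", ":"))


@dataclass(frozen=True)
class PhenotypeRule:
    """Cohort rule: require ``include``, veto preceding exclusion patterns."""

    include: PatternSignature
    exclude_preceding: tuple[PatternSignature, ...] = ()
    temporal_constraint: Optional[DurationBounds] = None


@dataclass(frozen=True)
class MiningResult:
    rule: PhenotypeRule
    support_target: float
    support_background: float
    confusion: tuple[int, int, int, int]   # (tp, fp, fn, tn) over patients


def block_signature(block: ContextBlock,
                    mode: SignatureMode = SignatureMode.SEMANTIC_TYPE
                    ) -> BlockSignature:
    """Project a context block to its signature.

    Within each wing the projection is order-insensitive (a sorted
    multiset); across the block's structures order is preserved.
    """
    mode = SignatureMode(mode)
    sig: list[StructureSignature] = []
    for v in block.structures:
        if mode is SignatureMode.SEMANTIC_TYPE:
            problems = tuple(sorted(ev.semantic_type for ev in v.problems))
            actions = tuple(sorted(ev.semantic_type for ev in v.actions))
        else:
            problems = tuple(sorted(ev.text for ev in v.problems))
            actions = tuple(sorted(ev.text for ev in v.actions))
        sig.append((problems, actions))
    return tuple(sig)


def signature_sequence(timeline: PatientTimeline,
                       mode: SignatureMode = SignatureMode.SEMANTIC_TYPE
                       ) -> list[BlockSignature]:
    """The timeline's context blocks, each reduced to its signature."""
    return [block_signature(b, mode)
            for b in extract_context_blocks(timeline)]


def find_matches(timeline: PatientTimeline,
                 signature: PatternSignature) -> list[int]:
    """Block positions where the pattern occurs, gap-free and possibly
    overlapping ("directly followed" means block-adjacent)."""
    seq = signature_sequence(timeline, signature.mode)
    return _matches_in(seq, signature.blocks)


def _matches_in(seq: Sequence[BlockSignature],
                pattern: Sequence[BlockSignature]) -> list[int]:
    k = len(pattern)
    return [i for i in range(len(seq) - k + 1)
            if tuple(seq[i:i + k]) == tuple(pattern)]


# ---------------------------------------------------------------------------
# rule evaluation

def _first_block_tap(timeline: PatientTimeline, block_pos: int
                     ) -> Optional[TemporalAnchor]:
    blocks = extract_context_blocks(timeline)
    if not blocks:
        return None
    return blocks[block_pos].structures[0].tap


def _window_satisfied(reference: TemporalAnchor, tap: TemporalAnchor,
                      window: DurationBounds) -> Optional[bool]:
    """Whether the possible distance reference->tap can fall in the window.

    None (indeterminate) when either anchor lacks a calendar interval.
    """
    if reference.interval is None or tap.interval is None:
        return None
    bounds = distance_bounds(reference, tap)
    if bounds.unit != window.unit:
        # compare in the window's unit via a coarse conversion table
        factors = {"minutes": 1, "hours": 60, "days": 1440,
                   "months": 43830, "years": 525960}
        scale = factors[bounds.unit.value] / factors[window.unit.value]
        lo, hi = bounds.min_units * scale, bounds.max_units * scale
    else:
        lo, hi = float(bounds.min_units), float(bounds.max_units)
    return lo <= window.max_units and hi >= window.min_units


def evaluate_rule(rule: PhenotypeRule,
                  timelines: Sequence[PatientTimeline]
                  ) -> list[Optional[bool]]:
    """Per-patient decision for a rule.

    A patient matches iff some include-match exists with no
    exclude-preceding match ending at or before its start, and (when a
    temporal window is set) the include match's first anchor can satisfy
    it.  ``None`` flags a patient indeterminate under the window because
    the relevant anchor is unresolved.
    """
    decisions: list[Optional[bool]] = []
    for timeline in timelines:
        seq = signature_sequence(timeline, rule.include.mode)
        include_matches = _matches_in(seq, rule.include.blocks)
        excl_ends: list[int] = []
        for excl in rule.exclude_preceding:
            excl_seq = (seq if excl.mode == rule.include.mode
                        else signature_sequence(timeline, excl.mode))
            excl_ends.extend(pos + len(excl.blocks)
                             for pos in _matches_in(excl_seq, excl.blocks))
        matched = False
        indeterminate = False
        first_blocks = extract_context_blocks(timeline)
        for pos in include_matches:
            if any(end <= pos for end in excl_ends):
                continue
            if rule.temporal_constraint is not None:
                reference = (first_blocks[0].structures[0].tap
                             if first_blocks else None)
                tap = first_blocks[pos].structures[0].tap
                ok = (None if reference is None else
                      _window_satisfied(reference, tap,
                                        rule.temporal_constraint))
                if ok is None:
                    indeterminate = True
                    continue
                if not ok:
                    continue
            matched = True
            break
        decisions.append(True if matched
                         else (None if indeterminate else False))
    return decisions


def confusion_counts(rule: PhenotypeRule,
                     target: Sequence[PatientTimeline],
                     background: Sequence[PatientTimeline]
                     ) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) over patients; indeterminate counts as non-match."""
    t = evaluate_rule(rule, target)
    b = evaluate_rule(rule, background)
    tp = sum(1 for d in t if d is True)
    fn = len(t) - tp
    fp = sum(1 for d in b if d is True)
    tn = len(b) - fp
    return tp, fp, fn, tn


# ---------------------------------------------------------------------------
# mining

def _ngrams(seq: Sequence[BlockSignature], max_len: int
            ) -> Iterable[tuple[BlockSignature, ...]]:
    for k in range(1, max_len + 1):
        for i in range(len(seq) - k + 1):
            yield tuple(seq[i:i + k])


def _support(pattern: tuple[BlockSignature, ...],
             seqs: Sequence[Sequence[BlockSignature]]) -> float:
    hits = sum(1 for seq in seqs if _matches_in(seq, pattern))
    return hits / len(seqs)


def _is_contiguous_subseq(small: tuple, big: tuple) -> bool:
    if len(small) > len(big):
        return False
    return bool(_matches_in(list(big), list(small)))


def mine_rules(target: Sequence[PatientTimeline],
               background: Sequence[PatientTimeline],
               min_support_target: float = 0.8,
               max_len: int = 2,
               mode: SignatureMode = SignatureMode.SEMANTIC_TYPE
               ) -> list[MiningResult]:
    """Mine ranked include/exclude phenotype rules from two cohorts.

    Enumerates every contiguous block n-gram (length <= ``max_len``)
    occurring in the target group; keeps those reaching
    ``min_support_target``; for each kept pattern that also appears in
    background patients, searches patterns frequently *preceding* it there
    (ending at or before an include-match start, support over those
    background matchers >= ``min_support_target``) and attaches the
    maximal ones as exclusion clauses.  Ranking: target support
    descending, background support ascending, pattern length descending,
    then serialized signature — fully deterministic.
    """
    if not target or not background:
        raise ValueError("target and background groups must be nonempty")
    if not 0 < min_support_target <= 1:
        raise ValueError("min_support_target must lie in (0, 1]")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    target_seqs = [signature_sequence(t, mode) for t in target]
    background_seqs = [signature_sequence(t, mode) for t in background]

    candidates: dict[tuple[BlockSignature, ...], float] = {}
    for seq in target_seqs:
        for pattern in _ngrams(seq, max_len):
            if pattern not in candidates:
                candidates[pattern] = _support(pattern, target_seqs)
    kept = {p: s for p, s in candidates.items() if s >= min_support_target}

    results: list[MiningResult] = []
    for pattern, support_t in kept.items():
        include = PatternSignature(pattern, mode)
        matchers = [seq for seq in background_seqs
                    if _matches_in(seq, pattern)]
        support_b = len(matchers) / len(background_seqs)
        exclusions: list[tuple[BlockSignature, ...]] = []
        if matchers:
            preceding: dict[tuple[BlockSignature, ...], int] = {}
            for seq in matchers:
                starts = _matches_in(seq, pattern)
                found = set()
                for q in _ngrams(seq, max_len):
                    if q == pattern or q in found:
                        continue
                    q_ends = [i + len(q) for i in _matches_in(seq, q)]
                    if any(end <= start for end in q_ends
                           for start in starts):
                        found.add(q)
                for q in found:
                    preceding[q] = preceding.get(q, 0) + 1
            qualifying = [q for q, c in preceding.items()
                          if c / len(matchers) >= min_support_target]
            # keep only maximal patterns: drop any that is a contiguous
            # sub-sequence of another qualifying pattern
            exclusions = [q for q in qualifying
                          if not any(q != other
                                     and _is_contiguous_subseq(q, other)
                                     for other in qualifying)]
        rule = PhenotypeRule(
            include=include,
            exclude_preceding=tuple(sorted(
                (PatternSignature(q, mode) for q in exclusions),
                key=lambda s: s.serialize())))
        results.append(MiningResult(
            rule=rule,
            support_target=support_t,
            support_background=support_b,
            confusion=confusion_counts(rule, target, background)))

    results.sort(key=lambda r: (-r.support_target, r.support_background,
                                -len(r.rule.include),
                                r.rule.include.serialize()))
    return results
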