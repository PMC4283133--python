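"""Block signatures, matching, rule mining and evaluation."""

import itertools
import random

import pytest

from vmodel.assembler import build_timeline
from vmodel.fixtures import (PATTERN_A, PATTERN_B, fig5_scenario,
                             generate_cohort)
from vmodel.model import (ClinicalEvent, ContextBlock, PatientTimeline,
                          extract_context_blocks)
from vmodel.patterns import (PatternSignature, PhenotypeRule, SignatureMode,
                             block_signature, confusion_counts,
                             evaluate_rule, find_matches, mine_rules,
                             signature_sequence)
from vmodel.temporal import DurationBounds, Unit


def _timeline_from_blocks(pid, block_sigs, start_month=1):
    """One singleton context block per signature, month-granular anchors."""
    events = []
    month = start_month
    for problems, actions in [sig[0] for sig in block_sigs]:
        year = 1990 + month // 12
        raw = f"{year % 100:02d}.{month % 12 + 1}"
        action_ids = []
        for k, tag in enumerate(actions):
            ev = ClinicalEvent(f"{pid}-a{len(events)}", f"{tag}_ev", tag,
                               len(events), raw)
            action_ids.append(ev.event_id)
            events.append(ev)
        for tag in problems:
            events.append(ClinicalEvent(
                f"{pid}-p{len(events)}", f"{tag}_ev", tag, len(events),
                raw, set(action_ids)))
        month += 2
    return build_timeline(events, patient_id=pid)


RED = PATTERN_A.blocks[0]
GREEN = PATTERN_A.blocks[1]
BLUE = PATTERN_B.blocks[1]
NOISE1 = ((("Purpose",), ("Plan",)),)
NOISE2 = ((("Purpose",), ("Other",)),)


def test_block_signature_projects_wing_multisets():
    events = [
        ClinicalEvent("p1", "dizziness", "Sx", 0, "02.8", {"a1", "a2"}),
        ClinicalEvent("a1", "CT", "Test", 1, "02.8"),
        ClinicalEvent("a2", "CT again", "Test", 2, "02.8"),
    ]
    timeline = build_timeline(events)
    block = extract_context_blocks(timeline)[0]
    assert block_signature(block) == ((("Sx",), ("Test", "Test")),)
    assert block_signature(block, SignatureMode.CONCEPT_LABEL) == \
        ((("dizziness",), ("CT", "CT again")),)


def test_block_signature_is_wing_order_insensitive_structure_order_preserving():
    t1 = _timeline_from_blocks("p1", [((("Sx",), ("Drug", "Test")),),
                                      ((("Sx",), ("Op",)),)])
    blocks = extract_context_blocks(t1)
    sig = block_signature(blocks[0])
    # brute force: all within-wing permutations give the same signature
    for perm in itertools.permutations(blocks[0].structures[0].actions):
        shuffled = ContextBlock(
            "b", blocks[0].structure_ids, blocks[0].link_evidence,
            (type(blocks[0].structures[0])(
                "s", blocks[0].structures[0].tap,
                blocks[0].structures[0].problems, list(perm)),))
        assert block_signature(shuffled) == sig
    two = block_signature(ContextBlock(
        "b", ("s1", "s2"), frozenset(),
        blocks[0].structures + blocks[1].structures))
    assert len(two) == 2


def test_find_matches_reports_adjacent_and_overlapping_positions():
    timeline = _timeline_from_blocks("p", [RED, GREEN, RED, GREEN])
    assert find_matches(timeline, PATTERN_A) == [0, 2]
    single = PatternSignature((RED,))
    assert find_matches(timeline, single) == [0, 2]
    repeated = _timeline_from_blocks("q", [RED, RED, RED])
    assert find_matches(repeated, PatternSignature((RED, RED))) == [0, 1]


def test_separated_blocks_do_not_match_a_bigram():
    timeline = _timeline_from_blocks("p", [RED, NOISE1, GREEN])
    assert find_matches(timeline, PATTERN_A) == []


@pytest.mark.parametrize("seed", range(6))
def test_find_matches_agrees_with_sliding_window_oracle(seed):
    rng = random.Random(seed)
    pool = [RED, GREEN, BLUE, NOISE1, NOISE2]
    blocks = [rng.choice(pool) for _ in range(rng.randrange(1, 8))]
    timeline = _timeline_from_blocks("p", blocks)
    k = rng.randrange(1, 3)
    start = rng.randrange(0, len(blocks) - k + 1) if len(blocks) >= k else 0
    pattern = tuple(blocks[start:start + k]) if len(blocks) >= k \
        else (rng.choice(pool),)
    sig = PatternSignature(pattern)
    seq = signature_sequence(timeline)
    oracle = [i for i in range(len(seq) - len(pattern) + 1)
              if all(seq[i + j] == pattern[j] for j in range(len(pattern)))]
    assert find_matches(timeline, sig) == oracle


# ---------------------------------------------------------------------------
# rule evaluation

def test_include_rule_matches_iff_pattern_found():
    with_a = _timeline_from_blocks("p", [NOISE1, RED, GREEN])
    without = _timeline_from_blocks("q", [NOISE1, NOISE2])
    rule = PhenotypeRule(include=PATTERN_A)
    assert evaluate_rule(rule, [with_a, without]) == [True, False]


def test_exclusion_vetoes_pattern_following_confounder():
    b_then_a = _timeline_from_blocks("p", [RED, BLUE, RED, GREEN])
    a_only = _timeline_from_blocks("q", [RED, GREEN, RED, BLUE])
    rule = PhenotypeRule(include=PATTERN_A, exclude_preceding=(PATTERN_B,))
    assert evaluate_rule(rule, [b_then_a, a_only]) == [False, True]


def test_temporal_window_filters_matches():
    timeline = _timeline_from_blocks("p", [NOISE1, RED, GREEN],
                                     start_month=1)
    near = PhenotypeRule(include=PATTERN_A, temporal_constraint=DurationBounds(
        0, 24, Unit.MONTHS))
    far = PhenotypeRule(include=PATTERN_A, temporal_constraint=DurationBounds(
        600, 1200, Unit.MONTHS))
    assert evaluate_rule(near, [timeline]) == [True]
    assert evaluate_rule(far, [timeline]) == [False]


def test_unresolvable_anchor_under_window_is_indeterminate():
    events = [
        ClinicalEvent("p-p0", "Sx_ev", "Sx", 0, "postop", {"p-a0"}),
        ClinicalEvent("p-a0", "Test_ev", "Test", 1, "postop"),
        ClinicalEvent("p-p1", "Sx_ev", "Sx", 2, "at follow-up", {"p-a1"}),
        ClinicalEvent("p-a1", "Drug_ev", "Drug", 3, "at follow-up"),
    ]
    timeline = build_timeline(events, patient_id="p")
    rule = PhenotypeRule(include=PATTERN_A, temporal_constraint=DurationBounds(
        0, 24, Unit.MONTHS))
    assert evaluate_rule(rule, [timeline]) == [None]


def test_evaluation_consistent_with_find_matches():
    cohort, background = generate_cohort(fig5_scenario(seed=11))
    rule = PhenotypeRule(include=PATTERN_A)
    for timeline in cohort + background:
        assert evaluate_rule(rule, [timeline]) == \
            [bool(find_matches(timeline, PATTERN_A))]


# ---------------------------------------------------------------------------
# mining

def _exhaustive_miner(target, background, min_support, max_len):
    """Independent oracle: enumerate all n-grams naively."""
    def seqs(timelines):
        return [signature_sequence(t) for t in timelines]

    def contains(seq, pattern):
        return any(tuple(seq[i:i + len(pattern)]) == pattern
                   for i in range(len(seq) - len(pattern) + 1))

    t_seqs, b_seqs = seqs(target), seqs(background)
    patterns = set()
    for seq in t_seqs:
        for k in range(1, max_len + 1):
            for i in range(len(seq) - k + 1):
                patterns.add(tuple(seq[i:i + k]))
    out = {}
    for pattern in patterns:
        support = sum(contains(s, pattern) for s in t_seqs) / len(t_seqs)
        if support >= min_support:
            b_support = (sum(contains(s, pattern) for s in b_seqs)
                         / len(b_seqs))
            out[pattern] = (support, b_support)
    return out


@pytest.mark.parametrize("seed", range(5))
def test_mined_patterns_and_supports_match_exhaustive_oracle(seed):
    spec = fig5_scenario(seed=seed, n_target=3, n_background=3)
    target, background = generate_cohort(spec)
    results = mine_rules(target, background, min_support_target=0.6,
                         max_len=2)
    oracle = _exhaustive_miner(target, background, 0.6, 2)
    mined = {r.rule.include.blocks: (r.support_target, r.support_background)
             for r in results}
    assert mined == oracle


def test_fig5_scenario_recovers_include_exclude_rule():
    target, background = generate_cohort(fig5_scenario(seed=0))
    results = mine_rules(target, background, min_support_target=1.0,
                         max_len=2)
    top = results[0]
    assert top.rule.include == PATTERN_A
    assert top.rule.exclude_preceding == (PATTERN_B,)
    assert top.confusion == (5, 0, 0, 5)
    assert top.support_target == 1.0


def test_identical_groups_cannot_be_separated():
    target, _ = generate_cohort(fig5_scenario(seed=4))
    results = mine_rules(target, target, min_support_target=1.0, max_len=2)
    for result in results:
        tp, fp, fn, tn = result.confusion
        assert tp == fp and fn == tn  # symmetry: no rule separates


def test_raising_min_support_never_adds_rules():
    target, background = generate_cohort(fig5_scenario(seed=2))
    lo = {r.rule.include.blocks
          for r in mine_rules(target, background, 0.4, 2)}
    hi = {r.rule.include.blocks
          for r in mine_rules(target, background, 0.8, 2)}
    assert hi <= lo


def test_planted_pattern_recovered_at_partial_support():
    from vmodel.fixtures import CohortSpec, PlantedPattern

    spec = CohortSpec(
        n_target=10, n_background=10,
        planted_patterns=(PlantedPattern(PATTERN_A, 0.9, "target"),),
        blocks_per_timeline=(4, 6), seed=13)
    target, background = generate_cohort(spec)
    results = mine_rules(target, background, min_support_target=0.8,
                         max_len=2)
    planted = [r for r in results if r.rule.include == PATTERN_A]
    assert planted
    measured = planted[0].support_target
    assert abs(measured * 10 - 9) <= 1  # within one patient of planted 0.9


def test_mine_rules_rejects_degenerate_inputs():
    target, background = generate_cohort(fig5_scenario(seed=1,
                                                       n_target=2,
                                                       n_background=2))
    with pytest.raises(ValueError, match="nonempty"):
        mine_rules([], background)
    with pytest.raises(ValueError, match="min_support_target"):
        mine_rules(target, background, min_support_target=0.0)
    with pytest.raises(ValueError, match="max_len"):
        mine_rules(target, background, max_len=0)


def test_confusion_counts_sum_to_cohort_sizes():
    target, background = generate_cohort(fig5_scenario(seed=6))
    rule = PhenotypeRule(include=PATTERN_A, exclude_preceding=(PATTERN_B,))
    tp, fp, fn, tn = confusion_counts(rule, target, background)
    assert tp + fn == len(target)
    assert fp + tn == len(background)
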