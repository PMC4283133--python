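# Methods

This note documents the modelling conventions, numerical choices and
known limitations behind `vmodel`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Temporal anchors

A temporal anchor point (TAP) pairs a verbatim expression with an
interval of possible times at minute resolution. The expression dialect
covers the forms that occur in narrative discharge summaries:

| form | example | granularity | interval |
|---|---|---|---|
| `YY` / `YYYY` | `86` | year | whole year |
| `YY.M` / `YYYY.MM` | `02.8` | month | whole month |
| `YY.M.D` | `02.8.4` | day | whole day |
| `YYs` / `YYYYs` | `1980s` | decade | ten years |
| `<n> <unit> ago/before` | `three days ago` | unit | that unit, against the document anchor date |
| `early/mid/late X` | `late 02.7` | as X | the first/middle/final third of X |
| `since/from X` | `from late 02.7` | as X | X, flagged open-start |
| anything else | `postop` | unknown | none (proximity hint) |

Conventions that the source expressions do not themselves fix, declared
once and configurable through the dialect section of the YAML config:

* **Century pivot 30.** Two-digit years ≥ 30 resolve to 19YY, < 30 to
  20YY, so `'86` → 1986 and `'02` → 2002, the only assignment consistent
  with the sixteen-year worked example.
* **Fuzzy thirds.** `early`/`mid`/`late` select equal thirds of the
  parent interval (by minutes). Any fixed convention would do; thirds are
  symmetric and testable.
* **Open starts.** `since/from X` anchors reasoning at X; the open end is
  *not* extended for ordering, which keeps `from late 02.7` strictly
  before `02.8`.
* **Named days** (holidays etc.) stay proximity hints unless an optional
  lexicon maps them to a date — the hint's contextual meaning is often
  worth more than a forced calendar position.
* **Parsing is total.** Unparseable non-empty strings become proximity
  hints; the empty string is a missing anchor. Nothing raises.

## Distance and ordering

`distance_bounds(a, b)` truncates both intervals to the finer of the two
granularities — floored at months, since a year-level anchor still spans
twelve months and the natural answer for a year/month pair is printed in
months — and reports `min = max(0, start(b) − end(a))`,
`max = end(b) − start(a)` in whole units. `'86` → `02.8` yields 188–199
months. `distance_estimate` is the midpoint converted at 12 months/year
and rounded half-up: (188+199)/2 = 193.5 months = 16.125 → 16 years.

`qualitative_relation` returns `before`/`after` only for strictly
disjoint intervals, `same_expression` for identical verbatim text (the
events share one TAP), and `undetermined` otherwise — including overlap,
containment and missing intervals. Within one v-structure the axiom
*problems start before actions* holds by construction and is exposed as
`problem_precedes_action`.

Both operations are verified against a brute-force oracle that
enumerates unit-truncated endpoint combinations; the suite runs it on
randomized anchors and the acceptance script on 10 000 seeded pairs.

## Assembly rules

* Role assignment is a pure function of (tag, explicit-causality flag);
  the flag is true iff the event carries outgoing causal links.
* Events sharing a verbatim expression share one anchor object. Within
  such a group, connected components of the problem→action link graph
  become separate v-structures (so two independent causal relationships
  under one date render as two v's, while problems sharing an action
  merge); unlinked events pool into a single residual structure, which
  may be one-winged.
* Events with empty `raw_time` inherit the nearest preceding expression:
  narration stays in order when time is omitted.
* Visit items attach to the first structure sharing their expression, or
  to the next structure in sequence; leftovers form a `visit_only`
  structure exempt from the nonempty-wing invariant.
* Ordering is an insertion sort under the partial chronological order:
  a pair of resolvable, disjoint anchors orders chronologically (a
  warning is logged when this contradicts narration order); all other
  pairs keep appearance order. Structure ids are assigned after
  ordering, so the timeline is invariant to input-list permutation.
* Cross-structure problem→action links (`link_problem_to_later_action`)
  must point forward; they feed context-block extraction and render as
  facing wing pairs. A linked Finding keeps its stored role.

Context blocks are maximal runs of consecutive structures joined by a
crossing causal link or a shared verbatim expression. Whether a block may
span an admission→discharge boundary is deliberately unconstrained.

## Rendering

The layout realises the dynamic scale: anchor marks sit at constant
`unit_spacing` regardless of elapsed time, so mixed year/month/day/hour
anchors share one baseline. Wing labels stack along the wing at fixed
pitch with a semantic tag box ahead of each same-tag run; residual box
overlaps are resolved by deterministic upward nudges, and the canvas
height follows the deepest wing, not the number of distinct concepts.
TAP labels are always the verbatim expression (a shared-expression
multi-v group gets one label, centred). SVG emission is pure string
assembly with fixed two-decimal formatting — identical inputs give
byte-identical output. Wing angle (default 55°, bounded to 15–75°),
spacing and colours are aesthetic defaults exposed in `RenderConfig`;
context-block shading exists behind a flag and is off by default.

## Pattern mining

Signatures abstract blocks either to semantic tags or to concept labels;
within a wing the projection is a sorted multiset, across a block's
structures order is preserved. Patterns are *contiguous* block n-grams
("directly followed" = block-adjacent); the miner enumerates all n-grams
up to `max_len`, keeps those with target support ≥ `min_support_target`,
and — for kept patterns with background matches — attaches as exclusion
clauses the patterns that occur ending at or before an include match in
at least `min_support_target` of the background matchers, filtered to
maximal patterns (a qualifying sub-pattern of another qualifying pattern
is dropped, so `red→blue` is reported rather than `red`, `blue` and
`red→blue` separately). Ranking is target support ↓, background support
↑, length ↓, then serialized signature — fully deterministic. Rule
evaluation accepts a patient iff some include match has no exclusion
ending before it and, when a temporal window is set, the match's first
anchor can lie within the window of the patient's first anchor; an
unresolvable anchor under a window flags the patient indeterminate
rather than silently non-matching. Gapped patterns, partial-block
(one-wing) patterns and significance testing are out of scope.

## Synthetic cohorts

`generate_cohort` emulates annotated event tables, not clinical
language: template texts, block-structured problem→action pairs along a
monotone date cursor, expressions sampled across the dialect
(year/month/day, fuzzy and semi-interval variants, relative phrases
consistent with the cursor, proximity hints, optional missing times).
Planted patterns occupy ⌈support × n⌉ timelines at a random position;
the include/exclude scenario (`fig5_scenario`, 5 target + 5 background
patients, 4–7 blocks each) plants the red→green bigram in every target
patient and, in background patients, the same bigram immediately after a
red→blue confounder. Noise block signatures are drawn from per-patient
slices of the signature pool, so cross-patient noise collisions cannot
fabricate a cohort-wide pattern — real cohorts enjoy no such guarantee,
which is why recovery results on synthetic data bound the miner's
correctness, not its real-world yield. What passing tests show is that
the machinery (parsing, assembly, block extraction, enumeration,
exclusion search) is exact at these scales; they say nothing about
annotation quality or causality extraction on real notes, which the
package does not attempt.

Problem sizes throughout (5–10 patients, ≤ 11 blocks per timeline,
10 000 oracle pairs, `max_len` 2) keep every check exhaustive and
sub-second while covering all code paths; supports and confusion counts
at these sizes are exact, not sampled.

## Known limitations

* No TimeML/TIMEX3 coverage, time zones, or probabilistic densities;
  the dialect covers the forms above and degrades to hints elsewhere.
* Causality is taken as annotated; the package never infers it.
* Mining is exhaustive enumeration — fine for block alphabets and
  `max_len` in the ranges above, not tuned for long event streams.
* The interchange schema rejects unknown fields by design; forward
  compatibility requires a schema-version bump.
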