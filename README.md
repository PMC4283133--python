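# vmodel

Narrative clinical notes — discharge summaries above all — carry the
richest phenotyping signal in an electronic health record, but their
events are anchored by temporal expressions a conventional timeline
cannot place: implicit years (`'86`), month-level dates (`02.8`), fuzzy
semi-intervals (`from late 02.7`), relative phrases (`three days ago`),
and pure proximity hints (`postop`). `vmodel` models such a history as a
sequence of **v-structures** on a *dynamic-scale* timeline: each glyph
anchors one temporal expression (TAP) and carries the *Problems* (why —
symptoms, purposes, explicitly causal diagnoses) on its left wing and the
*Actions* (what was done) on its right wing, with administrative *Visit*
items attached. Runs of causally linked structures form **context
blocks**, and recurring block patterns across a patient cohort can be
mined into include/exclude phenotype rules.

The package is aimed at clinical-informatics researchers who already have
annotated events (the 14-tag semantic taxonomy: Purpose, Sx, Dx, Finding,
Drug, Op, Other, Plan, Test, Tx, Adm, Death, Disch, Visit) and want a
tested, deterministic pipeline from events to timeline, SVG and cohort
rules. It does **not** do NLP: events arrive pre-extracted.

## The model in brief

* **TAP semantics.** Every temporal expression maps to a granularity-aware
  interval of possible times: `'86` ↦ [1986-01-01, 1986-12-31],
  `02.8` ↦ August 2002, `late 02.7` ↦ the final third of July 2002.
  Unresolvable phrases stay verbatim as proximity hints.
* **Distance bounds.** For anchors *a*, *b* with intervals truncated to
  the finer granularity *u* (floored at months),
  min = max(0, start(b) − end(a)), max = end(b) − start(a), in whole
  units of *u*. For `'86` vs `02.8` this gives 188–199 months
  (15 y 8 m – 16 y 7 m); the half-up-rounded midpoint is the *estimate*,
  "about 16 years".
* **Roles.** Sx/Purpose → Problem; Dx/Finding → Problem iff the text
  states them as a cause, else Action; Drug/Op/Other/Plan/Test/Tx →
  Action; Adm/Death/Disch/Visit → Visit. Problems precede their Actions
  by construction, even under a shared expression.
* **Assembly.** Events sharing a verbatim expression share a TAP; each
  distinct causal relationship within the group becomes its own
  v-structure; structures order chronologically where intervals decide
  and by narration order otherwise.
* **Mining.** Timelines reduce to context-block signature sequences;
  contiguous n-grams frequent in the target cohort become include
  patterns, and patterns that frequently *precede* them in background
  matchers become exclusion clauses ("include pattern A, exclude A
  following B").

## Worked example

The packaged worked example (`vmodel.fixtures.figure3_fixture()`) is a
gastric-cancer history: a 1986 operation (`TG c Roux-en-Y anastomosis`,
TAP `'86'`), chief complaints `from late 02.7` causally linked to the
August 2002 work-up (`Br. MRI`, `r/o CRP diagnosis`, `NTR of tm.`,
shared TAP `02.8`), and `FAM` chemotherapy anchored only by `postop`.

```sh
$ vmodel reason --a "86" --b "02.8"
relation: before
distance: 188-199 months
estimate: about 16 years
```

188–199 months is the possible-distance range between the two operations
(15 years 8 months to 16 years 7 months); 16 years is the rounded
midpoint estimate. In Python:

```python
>>> from vmodel import parse_tap, distance_bounds
>>> from vmodel.fixtures import figure3_fixture
>>> from vmodel.model import extract_context_blocks
>>> t = figure3_fixture()
>>> [v.tap.raw_text for v in t.structures]
['86', 'from late 02.7', '02.8', 'postop']
>>> [b.structure_ids for b in extract_context_blocks(t)]
[('s1',), ('s2', 's3'), ('s4',)]
```

The complaint structure and the work-up structure fuse into one context
block because of the stated causal link. A full synthetic cohort round
trip (target patients carry a red→green block bigram; background
patients carry it only after a red→blue bigram):

```sh
vmodel simulate --seed 9 -o cohort/
vmodel mine --target cohort/target --background cohort/background \
       --min-support 1.0 -o rules.json
```

The top-ranked rule in `rules.json` includes the red→green bigram,
excludes it when preceded by red→blue, and classifies all 10 synthetic
patients correctly (`"confusion": {"tp": 5, "fp": 0, "fn": 0, "tn": 5}`).

Timelines render to deterministic SVG (`vmodel build` then
`vmodel render`); Problem wings are red (`#CC0000`), Action wings blue
(`#0033CC`), anchor spacing is constant regardless of elapsed time.

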