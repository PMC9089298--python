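# Methods

## Model

`nanoits` is a rule-based decision system, not a fitted statistical model.
Its state is split into a static **knowledge base** (KB) and a dynamic
**dossier**; one ITS step is a pure function of the pair.

A KB declares:

* **modules** with a product scope (medical device, medicinal product, or
  both);
* **category endpoints**, qualitative (an explicit label set) or
  quantitative (a declared domain partitioned into class bins);
* **assays**, each with the endpoints it measures, a four-component ordinal
  characteristic profile, and an optional applicability rule;
* **selection rules** that scope a module or endpoint by product-level
  properties.

A dossier holds the product header, the nanomaterial components (layers,
CAS numbers, concentrations), one fact state per scope (the whole
nanomaterial plus each component), and raw measurement records. Header
descriptors (administration route, contact type/duration, dermal systemic
exposure, …) are exposed to the rule engine as ordinary endpoint facts, so
one rule vocabulary serves scoping and filtering alike.

## Three-valued semantics

Atoms test one endpoint: `class_is` / `class_in` compare the assigned
class label(s); `range_within` asks whether the endpoint's value lies in a
closed interval, using the raw numeric value when one is recorded and the
assigned class's bin otherwise (bin ⊆ range → TRUE, bin ∩ range = ∅ →
FALSE, partial overlap → UNKNOWN). Unassigned endpoints evaluate UNKNOWN.
Connectives follow Kleene's strong three-valued logic: NOT swaps
TRUE/FALSE and fixes UNKNOWN; AND and OR are min and max over
FALSE < UNKNOWN < TRUE.

Kleene evaluation is linear-time and order-independent but does not detect
tautologies (`A OR NOT A` over an unknown `A` stays UNKNOWN). The
supervaluation alternative — definite only when all completions agree — is
implemented as `eval_rule_oracle` by brute-force enumeration (capped at
4096 completions) and used purely as a test oracle: whenever the Kleene
evaluator is definite the oracle provably agrees, which the suite checks on
10⁴ random rule/fact pairs. Choosing Kleene for production keeps
evaluation cheap and sound; the price (occasional UNKNOWN where a
tautology exists) is conservative in the right direction, because
filtering excludes only on definite FALSE.

Blame assignment for traces is polarity-aware: an exclusion cites the atoms
that force the root FALSE, which under a NOT means atoms that evaluated
TRUE (e.g. "particle classification = metal oxide" under the fractionation
assays' negated rule).

## Class bins and boundaries

Bins are left-closed/right-open by default, matching the published size
classes (small < 30 nm, mid-low [30, 60) nm, mid-high [60, 200) nm, big
≥ 200 nm), with per-class inclusivity overrides. The published surface
charge classes use strict inequalities on all three classes, which leaves
ζ = ±10 mV unassigned; here the neutral class owns both boundaries
([−10, 10] mV) so the positive/negative classes keep their strict
inequalities. Each quantitative endpoint declares an explicit domain
(size: (0, 10⁴] nm; ζ: [−200, 200] mV; PDI: [0, 1]; RI: [1, 5]); values
outside the domain are errors, not a class. Validation checks that bins
are non-empty, non-overlapping, and cover the domain exactly, with every
shared boundary owned by exactly one side.

## Prioritization

Each characteristic class maps to 1 (low), 2 (medium), 3 (high) and

    priority = duration + cost + (3 − resolution) + expertise ∈ [3, 11],

lower better: duration, cost, and expertise are desirable when low while
resolution is desirable when high, hence its reversal. Assays are presented
in two groups — resolution class low versus medium/high — ranked ascending
by priority within each group with the assay id as a deterministic
tie-break (no canonical tie order exists; determinism is needed for
reproducible output). Assays whose rule is UNKNOWN are ranked alongside
applicable ones but flagged `possibly_applicable`, so an empty dossier
yields the complete catalogue.

## Measurements and characterization

Measurement records never mutate fact states implicitly; a class is
asserted either directly or by an explicit `derive_characterization` call
that aggregates the endpoint's records (median by default — robust to a
bad replicate — with mean and latest-timestamp as alternatives), classifies
the aggregate, and stores provenance (records used, statistic, aggregate,
class). The derived numeric aggregate is also kept as the endpoint's value
so range atoms resolve definitely. Re-deriving with unchanged records is a
no-op.

Classification honours the selection tree: single-choice endpoints reject a
second sibling unless an explicit replace flag is passed (one cannot be
both liquid and powder); multi-choice endpoints accumulate a label set, and
`class_is` over a multi-selection is membership with a closed-world reading
of the selected set.

## Packaged knowledge base and case studies

The shipped KB contains the endpoints and rules stated in the published
methodology: the two-branch tracking-analysis rule (low RI with a
[60, 1000] nm window, or high RI with [30, 1000] nm), the DLS rule (size
below 1000 nm and polydispersity not high), the metal-oxide exclusion for
the three fractionation/chromatography assays, and the dermal/no-systemic
rule for the in chemico skin-sensitisation assay, used both as an
endpoint-scoping rule and as that assay's applicability rule. The
"size = 60 / 1000" figures in the tracking-analysis rule are read as a
measurable-range constraint (the asserted size classes must be compatible
with the window), which is the only reading under which a very small
particle excludes the assay.

Quantities the published material does not fix were chosen once and are
marked as fixture choices in the KB file:

* **SLS minimum size**: working window [60, 10⁴] nm. Together with the
  iron-oxide case's size class mid-low ([30, 60) nm) this reproduces the
  published outcome in which SLS is excluded for both iron-based cases on
  small size while tracking analysis survives for the iron-oxide device.
* **PDI bins**: low < 0.1, medium [0.1, 0.3), high ≥ 0.3 — the
  conventional DLS reading of the polydispersity index.
* **Characteristic profiles**: not published per assay; chosen so that the
  empty case ranks DLS (5) and SLS (6) first, followed by NTA (8) and the
  fractionation techniques (9–11), all within the low-resolution group.
* The iron-oxide dossier asserts a high refractive index (iron oxides are
  well above 1.6), making tracking analysis definitely applicable; the
  iron-carbohydrate dossier leaves RI unassigned, so its tracking-analysis
  exclusion trace cites only the size atoms.

## Synthetic generators

`generate_random_kb` / `generate_random_dossier` build seed-deterministic
inputs for property tests: random contiguous bins over random domains,
random well-formed constant-free rules (depth ≤ 6), random class
assignments with a completeness probability, plus a consistent in-bin
numeric value for assigned quantitative endpoints. They emulate structural
variety (rule shape, bin layout, knowledge sparsity), not scientific
realism: random rules are not expert rules, and passing property tests
shows the engine's logic is sound and monotone, not that the packaged rule
content is complete for any real product class.

## Numerical and design choices

* Rule trees are finite; AND/OR require ≥ 2 children; serialization is
  nested `and`/`or`/`not`/`atom` maps (no infix parser).
* The oracle enumeration cap is 4096 completions; property tests keep
  expressions within it.
* Boundary recovery in the acceptance script bisects `classify_value`
  transitions to 10⁻⁹ and the DLS ceiling to 10⁻⁶ before rounding.
* Problem sizes: 10⁴ rule/fact pairs for the soundness check, 25 random
  fact-growth sequences, ~4×10³ grid points for partition coverage, 10
  random KBs for empty-knowledge completeness — all chosen to run in
  seconds while exercising every code path.
* Reports carry no timestamps, so identical inputs render byte-identical
  text and JSON; dossier writes are atomic (temp file + rename).
* The engine never decides that "enough information" has been gathered;
  every step returns the current recommendation and leaves stopping to the
  user.

## Limitations

* Only the published rules are packaged; the full module-selection rule
  sets derived from ISO/ICH documents and the complete immunotoxicity rule
  base are not public, so the immunotoxicity module here is mechanically
  complete but sparsely populated.
* Assay maturity/SOP metadata and development-stage scenarios are not
  modelled.
* `class_in` over multi-choice selections uses a closed-world reading of
  the selected set; if selections are meant to be partial, FALSE verdicts
  may be too eager (the packaged KB uses single-choice endpoints only).
* No web interface or multi-user collaboration: files and the CLI are the
  interface.
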