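# Methods

## Outcome

The unit of analysis is one motor-vehicle crash attended by an emergency
ambulance. The binary outcome — "an L&S response was needed" — is a
retrospective composite: the transport priority from the scene to an
emergency department was L&S, **or** anyone died on-scene or in transit,
**or** anyone met at least one clinical dispatch indicator. The indicator
table shipped as a default (`IndicatorRuleSet.default()`: GCS < 13,
systolic BP < 90 mmHg, respiratory rate < 10 or > 29, intubation,
adrenaline) is *illustrative only*; it preserves the structure of the rule
(named threshold predicates over interventions, medications and
observations) without claiming clinical authority, and is meant to be
replaced by a locally governed list. Labelling is strict: an absent
clinical field or indicator flag raises an error rather than defaulting to
"no". There is no accepted gold standard for retrospectively deciding who
needed an L&S response; every result is conditional on this composite.

## CHAID growth

Predictors are categorical (dichotomous, nominal, ordinal); continuous
variables (time of day) are discretised once at load time into
equal-frequency bins (default 10) and treated as ordinal thereafter.
Missing values form a reserved floating category that participates in
merging like any other, exempt from ordinal adjacency.

Per node and candidate variable:

* **Merge phase.** Each observed category starts as its own group. The
  allowable pair (any pair for nominal; adjacent groups only for ordinal;
  the floating missing group with anyone) whose 2×2 group-vs-outcome table
  has the largest Pearson χ² p-value is merged while that p-value exceeds
  `alpha_merge`. Ties on the p-value resolve to the first pair in span
  order, making the procedure deterministic. There is no re-split step
  after merging (SPSS offers one; omitted for simplicity and
  reproducibility).
* **Undersized groups.** After the significance-driven phase, any group
  smaller than `min_child` is merged with its most similar allowable
  partner. Without this step, rare dispatch codes (several Protocol 29
  codes cover 1–8 crashes) leave tiny groups, every candidate fails the
  child-size requirement, and the MPDS-only model cannot split at all.
  This mirrors the standard SPSS treatment of rare categories. The public
  `merge_categories` applies it only when a minimum group size is passed
  (tree growth passes `min_child`), so the bare greedy rule remains
  directly testable.
* **Score and adjust.** The merged r×2 table is scored by Pearson
  X² = Σ(O−E)²/E, df = r−1, with the upper-tail probability from the χ²
  distribution (`scipy.stats.chi2.sf`). The Bonferroni multiplier counts
  the partitions of the c observed categories into r groups: the Stirling
  number of the second kind S(c, r) for nominal variables, C(c−1, r−1)
  contiguous partitions for ordinal ones, both computed in exact integer
  arithmetic. When the floating missing category is present it is counted
  in c under the same formulas (the original CHAID literature has a
  separate floating-category count; the difference only rescales p_adj of
  candidates that all contain the missing category, and the simpler rule
  keeps the multiplier auditable against brute-force enumeration).
* **Split selection.** Candidates whose grouping would create a child
  below `min_child`, or that collapse to one group, are dropped; the
  smallest Bonferroni-adjusted p-value wins if it is ≤ `alpha_split`, ties
  broken by declared variable order. A node splits only if it has at least
  `min_parent` records, both outcome classes present, and depth below
  `max_depth`. When a first variable is forced (the MPDS code in families
  A, B and D), it is the only root candidate; deeper nodes use the full
  list.

Defaults: `alpha_merge = alpha_split = 0.05`, `min_parent = 100`,
`min_child = 50` — the SPSS Decision Trees defaults, since the source
analysis names the software but not its settings. All are configurable.

Classification routes a record to a leaf; a value not covered by any merged
group (missing, or unseen at training time) follows the group containing
the missing label, and if none exists routing stops at the current node and
uses its class distribution. A node predicts L&S iff p̂·c_fn ≥ (1−p̂)·c_fp,
with ties predicting L&S (safety-first); a leaf with no positive training
cases (p̂ = 0) never predicts L&S at any finite ratio. Costs deliberately do
not influence growth — growth is χ²-driven — so one tree per family serves
the whole cost sweep; this matches a report structure of one family × many
ratios.

## Cost sweep and selection

Integer ratios 1:k, k = 1, 2, …, are swept until under-triage reaches 0%
(equivalently, every record is dispatched L&S once the last negative leaf
flips), with a safety cap (default 100) that flags rather than silently
truncates. Because leaves flip in decreasing order of p̂, under-triage is
non-increasing and over-triage non-decreasing in k — asserted on every run.
Consecutive ratios with rates equal to one decimal place are collapsed to
ranges ("1:4 to 1:5") in the report.

Selection treats "closest to the ACS COT prescription" (under ≤ 5%, over
25–35%) as *front-loaded*: degenerate all-positive rows are excluded, and
among rows with under-triage ≤ 5% the minimum under-triage wins, ties
broken by minimum over-triage. The alternative reading — minimise
over-triage subject to the under bound — is defensible but would prefer a
higher-under model; the front-loaded rule reflects how EMS weigh the risk
of a missed time-critical patient. Per-row compliance flags against the
full benchmark are reported regardless of selection.

## Synthetic data

The real linked ambulance–police dataset is not available, so generators
emulate its printed margins:

* **fixture-faithful** — the joint (dispatch code × outcome) counts equal
  the embedded code table exactly (10,200 / 1,771 / 11,971); crash
  characteristics are drawn independently *given the outcome class* from
  the characteristic table, with each block's deficit versus the cohort
  total realised as item-level missingness (e.g. ~33% for accident type,
  ~61% for atmosphere). Only row order and the characteristic draws depend
  on the seed, so the all-positive baseline (85.2% / 0.0%) is exact at
  every seed.
* **marginal-independent** — features from pooled marginals, outcome an
  independent Bernoulli(1771/11971); a null dataset.
* **planted-tree** — features from pooled marginals, outcome drawn from
  per-leaf probabilities of a user-specified tree (JSON-serialisable);
  missingness applied afterwards if configured.

Variables the characteristic table does not print (raining as a separate
dichotomy, speed limit, traffic control, intersection type, time of day)
receive fixed, outcome-independent distributions chosen to look like an
urban road network with commuter peaks; they exist so the full declared
schema is populated, and they carry no signal.

What passing tests on these data do **not** show: the class-conditional
independence assumption erases the real correlations *between*
characteristics (a rollover crash is presumably also more often
single-vehicle), so the grown trees' interior structure, the exact
per-ratio rates, and the selected family are properties of the synthetic
joint, not of the study cohort. Quantities driven only by the margins —
the all-positive baseline, sweep termination, monotonicity, the maximum
observed depth of unlimited trees — are faithful.

## Numerical choices

* χ² p-values: Pearson statistic accumulated only over cells with positive
  expected counts; a table with a zero outcome column returns X² = 0,
  p = 1. Cross-checked against an independent contingency routine to 1e-10.
* All tie-breaks (merge pairs, split variables, group order) are total and
  documented, so identical data + configuration give bit-identical tree
  JSON.
* Percentages with zero denominators: over-triage is 0 when nothing is
  predicted positive, under-triage is 0 when everything is — matching the
  convention that an all-L&S dispatch policy has 0% under-triage.
* Seeds: `numpy.random.default_rng`; the missingness stream is offset from
  the sampling stream so the same seed never reuses draws.

## Problem sizes

The bundled experiments use the cohort size for sweeps (11,971), 20,000
records for monotonicity checks across ratios 1–30, and 20 replicates of
50,000 records for planted-structure recovery (the acceptance script uses
10 replicates); these sizes give binomial tolerances a few times smaller
than the effects they probe.

## Known limitations

* The composite outcome and illustrative indicator set are unvalidated;
  results are conditional on them.
* No pruning or cross-validation: rates are apparent (resubstitution)
  rates, as in the source analysis.
* Greedy merging is not exhaustive; the Bonferroni multiplier for
  floating-missing candidates is the plain nominal/ordinal count.
* The exact published multi-ratio table and 58-node tree derive from the
  unreleased linked dataset and are out of reach by design; this package
  reproduces the method and the margin-driven quantities, not that joint
  distribution.
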