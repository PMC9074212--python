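# mvctriage

Decision-tree triage of **lights-and-sirens (L&S) ambulance dispatch** to
motor vehicle crashes (MVCs).

When a bystander calls an ambulance to a crash, the dispatcher must decide
whether to send the highest-priority, lights-and-sirens response. Sending it
to a low-acuity crash wastes a scarce resource (*over-triage*); withholding
it from someone at risk of death delays care (*under-triage*). This package
asks whether crash characteristics a layperson can report over the phone
(rollover, anyone trapped, road surface, ...) — on top of the Medical
Priority Dispatch System (MPDS) Protocol 29 code already assigned during the
call — can identify the crashes that truly need an L&S response.

It is aimed at EMS researchers and dispatch-system analysts who want a
fully tested, reproducible implementation of the method on data with the
published cohort's marginal structure, or on their own crash data.

## Method

Trees are grown with **CHAID** (Chi-square Automatic Interaction
Detection) against a binary outcome *y* = "L&S response needed":

1. For each candidate predictor *X* at a node, greedily merge categories:
   repeatedly merge the pair of groups whose 2×2 (group × *y*) table has the
   largest Pearson χ² p-value, while that p-value exceeds α_merge.
   Ordinal predictors only merge adjacent categories; a floating
   missing-value category may merge anywhere.
2. Score the merged r×2 table by X² = Σ(O−E)²/E with df = r−1, and adjust
   the p-value by a Bonferroni multiplier B — the number of ways *c*
   observed categories reduce to *r* groups (the Stirling number S(c, r)
   for nominal predictors, C(c−1, r−1) for ordinal ones):
   p_adj = min(1, B·p).
3. Split on the predictor with the smallest p_adj if p_adj ≤ α_split,
   subject to minimum node sizes; recurse.

Misclassification costs enter at classification time only: with a false
negative costing *k* times a false alarm (ratio 1:*k*), a leaf with L&S
share p̂ predicts L&S iff p̂·k ≥ 1−p̂. Sweeping k = 1, 2, … trades
under-triage (1 − NPV) against over-triage (1 − PPV) until every crash is
dispatched L&S. Five model families are swept: **A** (MPDS code only,
depth 1), **B** (MPDS forced first + characteristics, depth ≤ 3), **C**
(characteristics only, depth ≤ 3), **D** (MPDS forced first + full
characteristic set, unlimited), **E** (full characteristic set, unlimited).
The best model is the non-degenerate row with the lowest under-triage at or
below the ACS COT bound of 5% (EMS triage is "front loaded"), ties broken
by lower over-triage.

The study's real linked ambulance–police dataset is not public, so the
package ships its printed marginal tables (11,971 crashes; 1,771 needing
L&S) and a synthetic-data module that emulates them — including an exact
**fixture-faithful** mode (the joint dispatch-code × outcome counts are
reproduced exactly) and a **planted-tree** mode that gives the grower a
recoverable ground truth.

## Worked example

```python
import mvctriage as mt

data = mt.sample_fixture_faithful(seed=1)          # 11,971 crashes
run = mt.run_all_families(data, mt.ChaidConfig())
print(run.report.head(8).to_string(index=False))
sel = run.selected
print(f"selected: model {sel.family} at 1:{sel.cost_ratio} "
      f"(over {sel.rates.over_triage_pct:.1f}%, under {sel.rates.under_triage_pct:.1f}%)")
```

```
Depth Model Misclassification costs  Over triage (%)  Under triage (%)  ACS COT compliant
    1     A                     1:1              0.0              14.8              False
    1     A                     1:2             66.6              13.2              False
    1     A                     1:3             68.9              12.5              False
    1     A              1:4 to 1:5             75.1               9.8              False
    1     A              1:6 to 1:8             76.5               9.3              False
    1     A             1:9 to 1:11             82.5               7.9              False
    1     A                    1:12             85.2               0.0              False
    3     B                     1:1             33.9              14.3              False
selected: model E at 1:28 (over 85.0%, under 2.8%)
```

Reading the report: at cost ratio 1:1 the depth-1 MPDS-only tree predicts
no crash as needing L&S (0% over-triage but 14.8% under-triage — one in
seven crashes needing urgent care would not get it). Raising the penalty on
missed L&S responses flips leaves to positive one by one until, at 1:12,
every crash is dispatched L&S (85.2% over-triage, the cohort's share of
crashes not needing L&S). Deeper trees reach low under-triage before
degenerating: the selected model holds under-triage at 2.8% at the price of
85.0% over-triage. No swept model attains the ACS COT over-triage window of
25–35% at compliant under-triage, which is the study's central trade-off.

The same pipeline is available from the shell:

```sh
mvctriage simulate --seed 1 --out cohort.csv
mvctriage report --data cohort.csv --schema cohort.csv.schema.json --out selection.json
```

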