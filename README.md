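# screeneval

Evaluation toolkit for LLM-assisted abstract screening in systematic
reviews.

Title/abstract screening is the first and most labor-intensive gate of a
systematic review: thousands of citations must each be marked *include* or
*exclude* against a PICOS eligibility frame (Population, Intervention,
Comparison, Outcomes, Study design). An LLM prompted to rate each citation's
relevance on an ordinal 1–5 scale can triage this workload — but only if its
operating characteristics against an expert gold standard are measured
properly. `screeneval` is the measurement half of that story, built for
methodologists running such evaluations: it handles the corpus pipeline, the
prompt/rating harness, multi-rater consensus, the diagnostic-accuracy panel,
ordinal ROC analysis, and paired bootstrap inference, plus a synthetic study
generator so every stage is testable offline.

## The statistics at the core

A rater's decisions against the gold standard reduce to a confusion table
(TP, FP, TN, FN), from which the panel computes sensitivity, specificity,
PPV, NPV, likelihood ratios (PLR = sens/(1−spec), NLR = (1−sens)/spec),
balanced accuracy, the Jaccard index TP/(TP+FP+FN), and the three
screening-specific quantities

```
FNR = FN/(TP+FN)      Proportion missed = FN/(FN+TN)      Workload saving = TN/N
```

An ordinal 1–5 rater induces five binary screeners (include iff rating ≥ t);
its ROC is the five-point empirical curve and its AUC the tie-aware rank
statistic P(rating⁺ > rating⁻) + ½·P(tie). The operating threshold maximizes
Youden's J = sensitivity + specificity − 1. Inter-rater agreement is Cohen's
κ; uncertainty and rater-vs-rater p-values come from a paired nonparametric
bootstrap that resamples *citations* (1000 replicates, percentile CIs), so
differences respect within-item correlation.

## Worked example

Reconstruct an ordinal rater's item-level data from its published cumulative
confusion counts, pick its operating threshold, and attach a bootstrap CI:

```python
import pandas as pd
from screeneval import (ConfusionCounts, evaluate, ratings_fixture_from_cumulative,
                        youden, binarize, bootstrap_ci, BootstrapConfig)

# cumulative (TP, FP) at thresholds >=2..>=5, out of 148 relevant / 1050 not
cum = {2: (141, 486), 3: (140, 366), 4: (107, 138), 5: (15, 13)}
ratings, gold = ratings_fixture_from_cumulative(cum, n_pos=148, n_neg=1050)

roc = youden(ratings, gold)
print(f"AUC = {roc.auc:.3f}, optimal threshold >= {roc.optimal_threshold} "
      f"(J = {roc.optimal_j:.3f})")

rep = evaluate(ConfusionCounts(tp=140, fp=366, tn=684, fn=8))
print("sensitivity", rep.rounded(2)["sensitivity"],
      "specificity", rep.rounded(2)["specificity"],
      "workload saving", rep.rounded(2)["workload_saving"])

items = pd.DataFrame({"gold": gold, "ai": binarize(ratings, roc.optimal_threshold)})
ci = bootstrap_ci(items, "sensitivity", "ai", BootstrapConfig(n_reps=1000, seed=1))
print(f"sensitivity 95% CI [{ci.ci_low:.2f}, {ci.ci_high:.2f}]")
```

prints

```
AUC = 0.864, optimal threshold >= 3 (J = 0.597)
sensitivity 0.95 specificity 0.65 workload saving 0.57
sensitivity 95% CI [0.91, 0.98]
```

Read: the rater's ratings rank relevant citations well ahead of irrelevant
ones (AUC 0.86); cutting at rating ≥ 3 catches 95% of the relevant studies
while correctly auto-excluding 57% of the corpus — at the cost of low
specificity (0.65), which is why a two-stage triage (`screeneval.triage`)
routes mid-band ratings to human review instead of auto-including them.

## Command line

The `screen-eval` CLI exposes one verb per stage: `ingest` (read RIS/CSV,
deduplicate, drop abstract-less records, per-topic subsample), `simulate`,
`screen` (mock backend), `consensus`, `evaluate`, `roc`, `compare`,
`reproduce-tables`, and `run` (end-to-end simulated study → JSON report
bundle with κ matrix, metric panels, CIs, p-values, and triage counts).

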