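# Methods

## Setting and data model

The package evaluates raters — human or LLM — who screen citations for a
systematic review. Each citation carries a title, abstract, reference type,
year and topic; each topic has a PICOS eligibility frame. Human raters give
binary include/exclude decisions; an AI rater gives an ordinal 1–5 relevance
rating. The gold standard is the decision of an expert pair after a third
expert adjudicates their disagreements. All evaluation reduces to paired
item tables: one row per citation, one column per rater, one gold column.

## Corpus pipeline

Deduplication uses a single key per record: the normalized DOI when present,
otherwise a normalized title (lowercased, punctuation stripped, whitespace
collapsed) plus publication year. First occurrence wins, so the result is
deterministic in input order and the filter is idempotent. "Missing
abstract" means empty after whitespace stripping. Per-topic sampling draws
without replacement from one generator seeded once, visiting topics in
sorted name order, so a (corpus, seed) pair always yields the same sample;
topics smaller than the requested size are taken whole.

## Rating harness

The prompt has four blocks in fixed order — role, task, article, PICOS —
and instructs the model to explain before rating and to answer with a
single JSON object `{"explanation": ..., "rating": n}`. Explain-then-rate
exploits autoregressive decoding: the rating token is conditioned on the
model's own stated reasoning. The parser scans the reply for the first
well-formed JSON object containing a `rating` key (earlier objects without
one are skipped; later ones ignored), coerces the rating to an integer and
validates it against the 1–5 scale. Parse and validation failures are
retried up to `max_retries` and then recorded as *missing with a reason* —
never imputed, and excluded from metrics with a logged count. A backend
transport failure after retries aborts with the partial results attached.

The deterministic mock backend rates `1 + min(4, overlap // 2)`, where
`overlap` counts distinct content words (length ≥ 4, stopword-filtered)
shared between the prompt's article and PICOS blocks. It is a pure function
of the prompt text; the `seed` argument exists only for interface parity
with stochastic backends. The live OpenAI-compatible backend implements the
same prompt-in/reply-out contract and is excluded from the test suite.

Two-stage triage maps ratings to labels: below `low` → auto-exclude, at or
above `high` → auto-include, otherwise human review. A missing rating goes
to human review — an unrated citation must never be silently excluded.

## Consensus and adjudication

Sensitive consensus includes a citation if any rater includes it, specific
if all do, voting on a strict majority. These are nested by construction
(specific ⊆ voting ⊆ sensitive), which forces sensitivity to be ordered
sensitive ≥ voting ≥ specific and specificity the reverse against any fixed
gold standard. Two policy choices the rules themselves do not determine:
an exact tie with an even rater count resolves to *include* (screening errs
toward sensitivity), and an item with any masked decision is dropped from
the consensus with a logged count rather than treated as an exclude vote,
which would bias the specific rule.

## Metric panel

All panel formulas are computed from the confusion table at full precision;
rounding (half-up, matching how printed tables round) happens only at
render time and raw values are always retained. Undefined ratios follow a
sentinel convention: 0/0 → `nan`, positive/0 → `inf` (a perfectly specific
rater's positive likelihood ratio renders as ∞). Cohen's κ uses the
standard two-rater marginal chance correction; when both raters are
constant and identical, chance agreement is 1 and κ is reported as the
`nan` sentinel rather than raising. A rater's "average agreement with the
panel" is the mean of its pairwise κ against each other rater.

## Ordinal ROC and threshold choice

The ROC of a 1–5 rater is the five-point empirical curve of the screeners
"include iff rating ≥ t". AUC is the tie-aware rank statistic (ties credit
½), which on an ordinal scale equals the trapezoidal area under the
empirical curve with (0,0) and (1,1) appended — a property test verifies
the identity, and the implementation is cross-checked against
scikit-learn's rank-based AUC in the suite. Youden's J is evaluated at all
five thresholds; ties across thresholds resolve to the *highest* tied
threshold, the more-excluding operating point, since at equal J the higher
cut saves more workload. Missing ratings are dropped with a logged count.

## Bootstrap

Resampling is at the citation level, paired across raters: each replicate
draws n items with replacement and evaluates every rater on the same
resample. Because the vector of joint (gold × rater responses) pattern
counts of such a resample is exactly Multinomial(n, empirical proportions),
replicates are drawn directly as multinomial count vectors and metrics
evaluated on counts — equal in distribution to index-level resampling, and
fast enough that 1000 replicates cost milliseconds. Defaults: 1000
replicates, percentile CIs at 95% (no bias correction — the simplest method
consistent with percentile-style printed intervals; BCa could be swapped in
behind the same interface). The two-tailed p-value for a difference is
2·min(share of replicates ≤ 0, share ≥ 0), floored at 1/B so a Monte Carlo
zero is never reported. Replicates where a metric is undefined (e.g. a
resample that loses all gold positives) are dropped and counted, with a
warning above 1%. Pattern categories are ordered by sorted rater name, so
comparing (a, b) and (b, a) uses the identical replicate stream: the
p-value is symmetric and the CI negates exactly. No multiplicity correction
is applied across a grid of metric comparisons; the panels report raw
two-tailed p-values and users should adjust if they intend family-wise
claims.

## Synthetic data

Exact fixtures: `fixture_from_counts` expands a confusion table into items
(order: gold-descending, prediction-descending, sequential ids — stable
diffs), and `ratings_fixture_from_cumulative` reconstructs per-rating class
counts by successively differencing cumulative TP/FP columns (rating-1
count = class total − the ≥2 count; a threshold absent from the input means
no items at exactly that rating). Both satisfy exact round-trip identities
for arbitrary valid inputs, property-tested.

Simulated studies use a one-factor probit model: item i has a shared
standard-normal difficulty u_i; rater r includes it iff
√ρ·u_i + √(1−ρ)·e_ir < Φ⁻¹(p_r), with p_r the rater's class-conditional
inclusion probability (sensitivity on positives, 1 − specificity on
negatives). The probit threshold preserves every marginal operating point
exactly for any coupling ρ ∈ [0, 1), while pairwise κ rises with ρ — the
simplest mechanism that makes agreement tunable independently of operating
points. The ordinal rater's rating is 1 + the number of cutpoints below a
class-conditional Gaussian latent score, sharing the same difficulty factor.

The default study spec mirrors the evaluation the package models: 1198
items at 148/1198 ≈ 12.4% relevance prevalence; three GP-like raters at
(0.55, 0.94), (0.55, 0.99), (0.74, 0.94) sensitivity/specificity; two
expert-like raters at (0.88, 0.98) and (0.90, 0.985); coupling ρ = 0.5,
chosen so simulated pairwise κ falls in the moderate-to-substantial band
reported for such panels. The ordinal rater's defaults (cutpoints 0.09,
0.39, 1.12, 2.26; positive class N(1.55, 0.85²), negative N(0, 1)) are a
least-squares-style eyeball fit of the published thresholded operating
points; they emulate the published rater qualitatively, not exactly, and
are documented as such. What the simulation does *not* model: real abstract
text (titles/abstracts are templated placeholders sufficient for the mock
backend), rater drift over time, topic-specific difficulty, or
non-Gaussian rating behaviour — so passing simulation tests demonstrates
the estimators' correctness and calibration, not real-world LLM
performance.

## Problem sizes and numerical choices

Published-result reproduction runs at the study's own scale (1198 items) and
is exact. Simulation-based checks use the sizes at which their statistical
tolerances are meaningful: operating-point recovery at n = 10⁴ (within 3
binomial SE), prevalence recovery at n = 10⁵, coupling monotonicity over
100 seeds at n = 600, and bootstrap coverage over 200 simulated studies of
n = 1198 with B = 1000 (nominal 95% CIs are required to cover truth 91–99%
of the time — percentile intervals for a proportion with ~150 effective
positives sit near 93–95%). Percentile interpolation between two infinite
order statistics (possible for likelihood ratios when a resample has zero
false positives) is reported as ∞, matching the table-rendering convention.

## Known limitations

- The live LLM backend is untested by design; only its contract is covered.
- RIS support covers the common tags (TY/TI/AB/PY/DO/KW/DB/ID) and
  continuation lines; exotic vendor dialects may need a custom reader.
- Percentile bootstrap CIs slightly undercover for extreme proportions;
  for metrics near 0 or 1 with few events, the printed intervals should be
  read accordingly.
- Kappa is the unweighted two-category statistic; ordinal (weighted)
  agreement between two 1–5 raters is out of scope.
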