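# Methods

This note documents the generative model, the protocol and metric
definitions, the statistical machinery, and the design choices made where
the underlying study left the design open.

## The annotation-panel model

The study conditions being emulated: 427 knee-MRI cases, balanced between
abnormal and normal (the odd case going to the abnormal side: 214/213), read
by ten radiologists whose accuracies span 78.69–84.07% (mean 80.77%), a
MobileNet-style machine with 81.72% accuracy serving as the fixed second
reader, and an InceptionV3-style machine (sensitivity 94.76%, specificity
76.27%) serving as the stand-alone benchmark. Each reading consists of a
binary call, a 5-level confidence and a 4-level perceived complexity;
ordinal level *k* of *L* is normalized to (k−1)/(L−1), the unique affine
map of the scale onto [0, 1].

Each case carries a latent difficulty `d ~ Beta(2, 2)` (symmetric, mean
0.5). Reader correctness uses **balanced-incidence sampling**: for each
reader and each gold class, the number of correct calls is the expected
count `p·n_class`, stochastically rounded, and the error set is chosen by
ranking cases on `slope·d + Gumbel(0, 0.11)` and failing the top-ranked
ones. This is equivalent to a per-case error model conditioned on its
marginal totals; it was chosen over independent Bernoulli draws because it
pins every reader's panel accuracy to its target within ±0.25 points
(binomial noise at n = 427 is ±1.9 points per reader, which would swamp the
roster's 0.2–0.6-point spacing), while preserving what matters
downstream: the per-case error probability decreases smoothly in
difficulty, shared difficulty correlates errors across readers (pairwise
correctness correlation ≈ 0.09 at the default slope 0.35), and slope = 0
recovers conditional independence (correlation within sampling noise of 0),
the regime in which best-of-three majority accuracy has the closed form
`3p² − 2p³`.

Ordinal self-reports come from latent Gaussian scales snapped to the grid:
confidence `0.62 + 0.05·correct − 0.35·d + bias + N(0, 0.15)` (5 levels),
complexity `0.35 + 0.72·d + N(0, 0.12)` (4 levels). The coefficients were
fixed once so that the panel-computed cautious-protocol thresholds land at
the study's operating point (mean pairwise confidence gap τ ≈ 0.17, mean
complexity δ ≈ 0.70) and the metadata associations have the documented
signs: per-case mean confidence correlates positively (Spearman ≈ +0.6),
mean complexity negatively (≈ −0.6), with the per-case success rate.
Machines report through a latent abnormality score s ∈ [0, 1]:
confidence = 2|s − 0.5| and complexity = 1 − confidence, quantized to the
ordinal grids, with the margin |s − 0.5| increasing when correct and
decreasing with difficulty. How the original study elicited machine
confidence/complexity is unpublished; this quantized-score convention is a
package choice. Likewise only the MobileNet machine's accuracy is
published, so its sensitivity/specificity split is taken symmetric.

Randomness: one root seed; the case stream and each reader's stream are
derived from `(seed, namespace, crc32(reader_id))`, so panels are
bit-reproducible and adding or removing a reader never perturbs the
readings of the others.

### What the generator does not emulate

Real panels have reader-specific biases (systematic over- or under-calling),
case-mix heterogeneity beyond a scalar difficulty, confidence scales used
idiosyncratically per reader, and machines whose errors cluster on case
types rather than a shared difficulty axis. Passing tests on synthetic
panels therefore demonstrate that the pipeline's algebra and inference are
correct under the stated model, and that the study's headline *directions*
are reproducible under it — not that the published table values would be
recovered on the undeposited annotation data. One visible consequence: the
synthetic confidence signal is more diagnostic of correctness than the real
readers' was, so the presumptuous and confidence-weighted protocols fare
comparatively better here than in the published tables.

## Protocols

All eight protocols consume an ordered team (first human, machine second,
human arbiter third). Escalation semantics, stated explicitly where the
source design leaves the two-reader case implicit: when only two readers
are involved and they agree, the team decision is their unanimous call;
whenever the third is involved, the decision is the simple majority of the
three (the weighted variants use the weighted majority over all involved).
Corner cases: an exact weight tie resolves by a configurable `tie_rule`
defaulting to abnormal-wins (erring toward sensitivity, the
screening-relevant direction); all-zero confidence weights (possible on the
normalized grid) fall back to the simple majority of the involved readers
and flag the outcome rather than fail; the cautious rule's
"more confident reader" shortcut requires a strict confidence ordering, so
an exact tie (possible only at τ = 0) escalates to the arbiter, as does any
case failing the `gap ≥ τ ∧ mean-complexity ≤ δ` predicate. Accuracy
weights are reader accuracies estimated on the full panel against gold — no
holdout, matching the study's usage. τ and δ default to the values computed
from the panel's human readers by the stated formulas (mean pairwise
absolute confidence gap; mean complexity); whether the machine joins that
average is configurable and off by default, since the published
formulas average over the ten humans.

## Metrics

Accuracy, sensitivity (over abnormal gold) and specificity (over normal
gold) are plain confusion-matrix rates; efficiency divides correct team
decisions by total judgments elicited, so it is bounded above by accuracy
and, for the majority protocols (2–3 judgments per case), lies between
accuracy/3 and accuracy/2. Composites — the harmonic mean of
sensitivity/specificity and `F₂(acc, eff) = 5·acc·eff/(acc + 4·eff)` — are
always computed per team and then averaged, never from averaged
components: composite-of-means differs from mean-of-composites, and the
study's protocol rows are team averages. Undefined rates (a gold class
absent from a stratum) propagate as NaN and are excluded from averages.

## Statistics

The one-sample and pooled two-sample t tests and the two-sample KS test are
implemented directly (scipy supplies only distribution functions) so each
is verifiable against independent references. The KS statistic is computed
in integer arithmetic on the pooled support, `max|i·m − j·n|/(n·m)` —
stated explicitly because team metrics live on a 1/427 grid and are heavily
tied. The p-value is exact for both n ≤ 25 via lattice-path counting with
exact integers (the no-ties null; conservative under ties), and uses the
finite-size-corrected large-sample KS distribution at the effective sample
size n·m/(n+m) otherwise. Pooled (not Welch) variance is the two-sample
default because it reproduces the study's printed df = 8 for the
weak-vs-strong reader comparison (t = 5.66); Welch is available. Note the
recomputed two-sided p for that comparison is ≈ 4.7×10⁻⁴, not the 0.002
printed in the source. Bonferroni families default to each result table's
visible comparison grid — 8 protocols per metric (experiment 1), 8×8 cells
per metric (experiment 2) — and are overridable; significance is read at
α = 0.05 on corrected p. Confidence intervals on protocol means are
t-based over team values.

## Problem sizes and determinism

Default runs use the study geometry: 427 cases, 90 teams (10·9 ordered
pairs), 20 + 20 teams in the split experiment. Monte-Carlo checks in the
test suite use 100–200 panel seeds at n = 427 and single panels at
n = 100 000 for the closed-form majority limit; the group-size sweep
enumerates all subsets up to C(10,5) = 252 (a cap with seeded subsampling
is available for larger rosters). Every pipeline stage is deterministic
given its seed; result manifests record output digests so a re-run can be
verified bit-for-bit on the full-precision columns.

## Known limitations

- Machines are fixed operating points; no score thresholds or ROC analysis.
- The generator's single difficulty axis cannot produce protocol-dependent
  error correlation structure (e.g. machine errors disjoint from human
  ones), which likely understates how much arbitration helps mixed teams.
- Exact KS p-values assume exchangeability without ties; with the heavy
  metric ties the reported p is conservative.
- Reading time and cost are not modelled; efficiency counts judgments only.
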