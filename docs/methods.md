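# Methods

## The problem and the model

In a slowly progressive disease such as knee osteoarthritis, the risk of
reaching the terminal clinical event (total knee replacement, TKR) within a
fixed horizon can only rise or stay flat as the disease advances; current
treatments do not reverse established structural damage. A conventional
classifier scores every scan independently and can therefore emit a *lower*
predicted risk for a later scan of the same knee — an epistemically
inconsistent prediction.

`progrisk` enforces the constraint in closed form. A trainable scorer `f`
maps a scan to an unbounded real score; the scan-1 risk is the ordinary
sigmoid, and the scan-2 risk is composed so the constraint holds for *any*
real scores:

* **RiskFORM1** (shared scorer):
  `ŷ₁ = σ(f(x₁))`, `ŷ₂ = 1 − (1 − σ(f(x₁)))(1 − σ(f(x₂)))`.
* **RiskFORM2** (dedicated second scorer `g`):
  `ŷ₂ = 1 − (1 − σ(f(x₁))) σ(g(x₂))`. Here `g`'s output is inversely
  related to risk (a large `g` score keeps the no-event probability large).

Both satisfy `ŷ₂ ≥ ŷ₁` because the second factor of the no-event
probability lies in (0, 1). Training minimises
`BCE(y₁, ŷ₁) + BCE(y₂, ŷ₂)` (natural log); subjects with only a baseline
scan contribute only the first term, and under RiskFORM2 such samples never
update `g`.

Two soft-constraint comparators are implemented for contrast, attached to
the unconstrained baseline (independent-sigmoid) loss:

* **RiskReg** — a margin loss `γ · max(0, m − (f(x₂) − f(x₁)))` on raw
  scores. The margin operates on the unbounded score (logit) scale: the
  default `m = 2.0` would be meaningless on the probability scale, where
  differences cannot exceed 1.
* **ConReg** — a Siamese contrastive (Hadsell-style) penalty on the
  penultimate-layer embeddings,
  `γ [(1 − s) d² + s · max(0, m − d)²]` with `d` the Euclidean embedding
  distance and `s = 1` when the two horizon labels differ. The margin is
  shared with RiskReg. The exact forms above are this package's declared
  defaults — deliberately the textbook version of each idea.

Defaults `m = 2.0`, `γ = 1.0`. Whether the weight γ multiplies the whole
penalty or enters the margin expression was an open choice; it is treated
as an outer multiplicative weight.

### Numerical choices

* Scores are clipped to ±500 before exponentiation and the sigmoid is
  evaluated in its two-branch stable form; probabilities are clamped to
  `[1e−7, 1 − 1e−7]` inside the cross-entropy.
* The compositions are evaluated in the algebraically equivalent additive
  form `ŷ₂ = ŷ₁ + (1 − ŷ₁)·q`, `q ∈ [0, 1]`. Adding a rounded non-negative
  term can never fall below the representable `ŷ₁`, so the ordering
  guarantee holds exactly in floating point (the product form
  `1 − (1−p₁)(1−p₂)` can violate it by ~1 ulp).
* Gradients of the pair loss with respect to the raw scores are closed
  form, e.g. `∂L₂/∂s₁ = (ŷ₂ − y₂) p₁ / ŷ₂` for both compositions; they are
  verified against central finite differences in the test suite.

## Labels, pairs and cohort construction

**Horizon labels.** The label of a scan at horizon `h` ∈ {1, 2, 4} years is
1 if the event occurs within `h` years of the scan (boundary inclusive — an
event at exactly `h` years counts positive; the convention had to be fixed
one way), 0 if the event is known to occur later or follow-up extends at
least `h` years event-free, and *undefined* when the subject is censored
earlier. Scans with undefined labels are excluded from training and
evaluation at that horizon.

**Pair selection.** Scan 1 is always the baseline scan. For subjects with
an observed event, scan 2 is the latest scan acquired 1–4 years before the
event; for event-free subjects it is the latest scan whose label at the
horizon is still defined. Subjects without an eligible second scan
contribute a single-scan sample. Pairs are grouped by label trajectory:
Set 1 (0→1, progression), Set 2 (0→0, stable negative), Set 3 (1→1, stable
positive). Set 3 is structurally empty at the 1-year horizon: a positive
baseline label implies the event precedes any scan one or more years into
the study, so no eligible second scan exists.

**Matching.** Each event subject is matched one-to-one to an event-free
subject with identical integer age (a configurable ±k widening exists for
sparse cohorts), identical sex and ethnicity, and baseline BMI within 10 %
*of the case's BMI* (the tolerance is anchored on the case). Matching is
solved as maximum-cardinality bipartite matching
(`scipy.sparse.csgraph.maximum_bipartite_matching`) rather than a greedy
pass, so the result is order-independent and no matchable case is
stranded. Controls are never reused across cases: matching is strictly
one-to-one.

**Nested splits.** Subjects are stratified by case/control and dealt into
7 outer folds; within each (stratum, outer fold) cell they are dealt again
into 6 inner indices. For outer fold `o` and inner index `i`, the test set
is fold `o`, validation is `{outer ≠ o, inner = i}`, training is the rest —
42 assignments with ≈ 5/7 : 1/7 : 1/7 proportions, each inner split
partitioning its outer-training pool. All assignment is subject-level and
deterministic given the seed.

## The synthetic cohort generator

The simulator emulates the statistical structure the method assumes, not
radiographic appearance:

* latent severity `s(t) = s₀ + rate·t` with `rate ≥ 0` (monotone by
  construction); the event occurs when severity first crosses `θ = 4`, the
  top of the grade scale;
* a 50/50 mixture of stable subjects (`rate = 0`) and progressors
  (`rate ~ U(0.2, 1.0)` per year), `s₀ ~ U(0, 2.5)`; subjects already past
  threshold at baseline are excluded (the usual prevalent-case exclusion);
* annual visits over 9 years with an absorbing 8 % per-visit drop-out, and
  no scan at or after the event — so "last available scan" selection is
  non-trivial and censoring is real;
* event dates are recorded on a quarter-year grid (clinic scheduling
  granularity, rounded up from the true crossing). This detail matters: with
  continuous event times and annual visits, the latest scan 1–4 years
  pre-event would carry a positive 1-year label with probability zero and
  the progression group would vanish at the 1-year horizon;
* an ordinal 0–4 grade (the Kellgren–Lawrence analog) bins severity at cuts
  1, 2, 3, 4, left-closed on the upper side;
* demographics are drawn in matched (progressor, stable) couples — shared
  integer age (50–64), sex, one of three ethnicity categories, log-normal
  BMI jittered within ±5 % for the couple's second member — so the exact
  matching constraints have support;
* payloads: either an 8-dimensional feature vector `w·severity + ε`,
  `ε ~ N(0, 0.5²)`, with `w` a fixed unit direction, or a grayscale
  "radiograph" of two bright bands whose gap (the joint-space analog)
  shrinks linearly with severity, plus pixel noise.

What the generator does **not** emulate: anatomical appearance and imaging
physics, nonlinear or intermittent progression, measurement-batch effects,
informative censoring, label noise in the event date, and any correlation
between demographics and progression rate. Passing tests therefore
demonstrate the *mechanics and statistics* of the method — the ordering
guarantee, the labeling/matching/splitting algebra, calibrated inference —
not clinical performance on real radiographs; absolute metrics from large
observational imaging cohorts are outside what a desk-scale synthetic
cohort can reproduce.

## Training

Reference scorers are intentionally small: a tanh MLP (one hidden layer of
16 units) for feature payloads and a 3-block CNN (3×3 convolution → ReLU →
2×2 average pooling, then a global-average-pooled linear head) for image
payloads, both plain numpy with hand-derived backpropagation and Adam
(lr 0.01, decoupled weight decay 1e−4, batch 32). The `Scorer` contract
(`forward`, `forward_cache`/`backward`, `embed`) allows a larger backbone
to be swapped in. Mixed batches of singles and pairs are allowed; absent
scan-2 terms are masked out of loss and gradient.

Model selection retains the parameters of the epoch with the best
validation AUROC (the selection metric had to be chosen; AUROC matches the
headline evaluation metric). Ensembling averages member *probabilities*
(not logits): the mean of member-wise ordered risk pairs is itself ordered,
so the guarantee survives ensembling. Per the nested protocol, each outer
test fold is predicted by the ensemble of its 6 inner models. Class
imbalance is handled by the matched design alone — no reweighting.
Hyperparameters are tuned, if at all, on the single designated inner fold
(outer 0 / inner 0 by default) and then frozen across all folds.

## Evaluation

All metrics are scan-level: every scan's risk is scored against its own
label, preventing the trivial inflation that would reward merely ranking
scan 2 above scan 1. AUROC is the Mann–Whitney statistic with tied pairs
counted ½; AUPRC is step-wise average precision over unique thresholds.
Confidence intervals are percentile bootstrap over 1000 scan-level
resamples (the interval type had to be chosen; degenerate one-class
resamples are skipped and counted). Formulation contrasts use DeLong's
structural-components test on paired scores, pooled over scan 1 and scan 2
observations — within-subject correlation between a subject's two scans is
thereby ignored, a deliberate simplification matching the scan-level
design. Subgroup analyses use four cohorts built from the pair sets
(C1 = Set 1; C2 = Set 1 ∪ Set 2; C3 = Set 1 ∪ Set 3; C4 = Set 2 ∪ Set 3;
single-scan subjects excluded), plus per-grade AUROC. Undefined metrics are
reported as missing, never as 0 or 0.5.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen as the smallest sizes at
which each property is sharply testable: the ordering fuzz uses 10⁵ score
pairs per formulation; metric oracles 1000 random instances of size ≤ 12;
DeLong null calibration 1000 replications at 300 scans; bootstrap coverage
500 replications of 100 scans (500 resamples each); the end-to-end
recovery five 400-subject cohorts at the 2-year horizon (the middle
horizon, where all three pair sets are populated) with the full 7×6 nested
protocol and 40 training epochs.

## Known limitations

* Only two scans per subject are composed; conditioning on longer scan
  histories is out of scope.
* The reference scorers are not meant to be competitive image models; the
  CNN exists to exercise the image path end to end.
* DeLong is applied pooled rather than per outer fold, and ignores the
  within-subject pairing of scan 1 and scan 2 (see above).
* The simulator's linear severity dynamics are the simplest structure
  satisfying the monotone-risk premise and are intended to be replaceable.
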