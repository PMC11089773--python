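# Methods

## Coordinate conventions

Predictions are thresholded with the inclusive rule score ≥ t; every
unique observed score is a threshold, so the final anchor always has
TP = P, FP = N (recall 1, precision = prevalence). Tie groups are formed
by exact floating-point equality of scores — never by an epsilon — so
anchor construction is deterministic and invariant to the order of input
rows. Users who want near-ties merged do it explicitly with
`round_scores` (CLI `--round-scores d`). The virtual origin
(TP = FP = 0) is a sentinel, not an anchor: precision 0/0 is never
fabricated. Whether surveyed tools use ≥ or > is not documented
uniformly; the package fixes ≥ as its reference convention and does not
promise threshold-rule agreement with any particular tool.

Labels are accepted only as {0, 1} integers or booleans; anything else
is rejected rather than coerced, because silent coercion (e.g. of a
{1, 2} encoding) flips the meaning of precision.

## The expectation interpolation

Between anchors flanking a tie group of ΔTP positives and ΔFP negatives,
the expectation methods place interpolated points at their expected
coordinates when all orderings of the tied entities are equally likely:
after x of the tied positives, the expected accompanying false positives
are s·x with s = ΔFP/ΔTP, giving

    prec(x) = (TP_A + x) / (TP_A + FP_A + (1 + s)·x),   x ∈ [0, ΔTP].

The continuous method integrates this exactly. With a = TP_A,
C = TP_A + FP_A, b = 1 + s,

    ∫₀^ΔTP prec(x) dx = ΔTP/b + (a − C/b)/b · ln(1 + b·ΔTP/C),

divided by P to express the area over recall. Two special cases: C = 0
(the segment from the virtual origin — the curve is constant at
ΔTP/(ΔTP+ΔFP), so a fully tied classifier scores exactly the prevalence)
and ΔTP = 0 (zero recall width, zero area). The closed form is verified
in the test suite against adaptive quadrature (`scipy.integrate.quad`)
to 1e-10 on randomized segments; `log1p` keeps the expression accurate
when b·ΔTP ≪ C. The discrete method evaluates the same curve at
x = 0, tp, 2·tp, …, ΔTP (default step tp = 1, the classical one point
per additional true positive; tp = 0.5 supported) and integrates the
chords; its area converges linearly in the step to the continuous value.
Singleton groups go through the same code paths — with ΔTP ≤ 1 the
formulas reduce to the no-tie case — so tied and untied data cannot
drift apart.

Per-curve areas are summed with `math.fsum` (compensated summation), so
AUPRC does not depend on segment count or accumulation order at double
precision.

## Start and coverage conventions

With the `derived` start the curve begins at the method's own limit at
recall 0: the first expectation segment's constant value
ΔTP₁/(ΔTP₁+ΔFP₁) for the expectation methods, the first anchor's
precision for linear and AP. The `fixed_0_1` convention — a documented
defect of several tools — forces the start point to (0, 1): this
changes the area for chord-integrated methods (linear, discrete
expectation), whose first chord then descends from precision 1, but for
the continuous curve and the AP step it only prepends a drawn point of
measure zero. On a balanced all-tied dataset the difference is exact:
linear with a (0, 1) start gives (1 + ½)/2 = 0.75 where every
expectation/AP method gives the prevalence 0.5.

`full_coverage = False` emulates tools whose PRC does not span recall
0→1: the drawn curve starts at the first observed anchor. This is a
defect of the curve, not of the area — AUPRC keeps the full integral,
because under the inclusive-≥ anchor construction the integration range
is always [0, 1] and a perfect classifier must score 1.0 under every
profile. The additional area a genuinely truncating tool would lose
(O(1/P) on realistic data) is outside what the profiles emulate.
Likewise `drop_anchors` (a plotting defect: interior anchor points left
off the curve) changes `curve_points()` but never the area.

`tie_order_sensitive` reproduces tools that sequence tied entities by
their input order and then treat the scores as distinct: every entity
becomes its own singleton anchor, the no-tie method applies throughout,
and the result depends — by design — on input row order. Putting actual
positives before actual negatives within a tie group maximizes the
emulated value; the reference profile is provably order-invariant.

Datasets with no negatives yield the constant curve precision ≡ 1 and
AUPRC 1 under every method; this is allowed with a warning rather than
an error (N = 0 is a legitimate degenerate universe; P = 0 is not, since
recall is undefined, and raises).

## Emulation profiles

Each profile bundles one tool's documented behaviour: connection method
without ties, connection method with ties, start convention, and the
defect flags above. The catalogue covers ROCR, Weka, scikit-learn
(curve+trapezoid and average-precision modes), PerfMeas, PRROC (discrete
and continuous expectation modes), TensorFlow, precrec, TorchEval,
MLeval, and yardstick (curve and AP modes), plus a defect-free
`reference` profile (continuous expectation, derived start). Profiles
emulate documented method combinations and convention flags only;
bit-exact agreement with third-party binaries is explicitly not
promised. TensorFlow's requirement that scores lie in [0, 1] is served
by the order-preserving `rescale_unit_interval` transform (CLI
`--rescale01`), which provably changes no anchor and no area.

AUROC is computed once, by trapezoids over the ROC anchor points with
tie groups crossed by a diagonal chord; this equals the Mann–Whitney
pair-counting statistic with half credit for ties, is identical across
profiles, and serves as the reference metric on which tools agree.

## Diagnostics

`score_all` evaluates every submission under every profile;
ranks within a profile are dense (1 = best, exact ties share a rank), so
tied leaders are representable. `rank_flips` enumerates all submission
pairs × profile pairs with strictly reversed AUPRC order — exhaustive
O(n²m²), which is the honest definition and cheap at leaderboard sizes.
Correlations between profile columns are reported both as Pearson on
AUPRC values and Spearman (rank-based); zero-variance columns yield NaN,
never 0, since a constant column carries no ordering information.

## Synthetic data

The generator produces the three score regimes that drive method
disagreement: `gaussian2` (negatives ~ N(0, 1), positives shifted by
`separation` — continuous scores, ties almost surely absent),
`discretized` (the same scores quantized to `n_levels` equal-width bins,
guaranteeing tie groups), `cluster_binary` (hard cluster membership:
scores in {1, 0}, exactly two tie groups, `separation` = the fraction of
positives inside the predicted cluster), and `random` (uniform scores
independent of labels). Identical configurations give byte-identical
output. What it does not emulate: correlated features, calibrated
probabilities, class-conditional score skew, or any real assay's
distribution — passing tests show the integration and convention
machinery is correct, not that any particular biological classifier is
well evaluated.

The fixture catalogue reproduces the *structure* of the illustrative
datasets used in the documentation and tests (tie groups of 3, 7, 2, 1
entities; an all-tied 32-positive/42-negative group; perfect separation;
a single positive ranked last); the score values themselves are
synthetic. The `flip_pair` fixture — an all-tied and a tie-free
submission over the same six entities with near-equal (within 0.015)
continuous-expectation AUPRC that linear and AP profiles rank in
opposite orders — was found by exhaustive search over six-entity
tie-free label orderings and is frozen for reproducibility.

## Known limitations and numerical notes

- The expected AUPRC of a *random-score* classifier exceeds the
  prevalence baseline at finite sample sizes: precision is convex in
  the accumulated false positives, so averaging the area over random
  orderings (Jensen) lies above the area of the average ordering — the
  all-tied classifier, which sits exactly at prevalence. Exact
  enumeration over all orderings at P=2/N=4 gives mean AUPRC 0.4438
  versus prevalence 1/3, and at P=50/N=450 the Monte-Carlo mean is
  ≈ 0.105–0.106 versus 0.1; scikit-learn's average precision shows the
  same finite-sample optimism on identical draws. The test suite pins
  the Monte-Carlo mean to the enumeration oracle rather than to
  prevalence; "no-skill AUPRC = prevalence" is exact only for the
  all-tied classifier or asymptotically.
- Problem sizes in the test and acceptance runs (instances ≤ a few
  hundred entities; 500 Monte-Carlo replicates at P=50/N=450; 100
  randomized quadrature segments) were chosen as the smallest sizes at
  which every contrast of interest is resolved far beyond its assertion
  tolerance; everything completes in seconds.
- Multiclass/multilabel evaluation, weighted AP, bootstrap confidence
  intervals, and ROC-space interpolation variants are out of scope.
  One-vs-rest looping is left to the caller.
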