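# prcmethods

Precision-recall curves and AUPRC under explicit, named conventions.

Binary classifiers in computational biology — cell-type predictors,
network-inference methods, diagnostic models — are routinely compared by
the area under the precision-recall curve (AUPRC). But "the" AUPRC is
not one number: evaluation tools differ in how they connect adjacent
curve points, how they treat tied classification scores, and where they
start the curve, and these choices shift AUPRC enough to reorder
competing classifiers while leaving AUROC untouched. `prcmethods` is a
reference implementation of the four anchor-connection methods in common
use, with exact tie-group semantics, emulation profiles that reproduce
the documented behaviour of widely used tools, and diagnostics that
quantify how much the choice of method changes values and ranks.

## The model

Thresholding at each unique observed score `t` (predict positive when
score ≥ t) yields cumulative counts (TP, FP) and hence one **anchor
point** (recall, precision) = (TP/P, TP/(TP+FP)). Entities sharing a
score form a **tie group** contributing increments (ΔTP, ΔFP) between
adjacent anchors. Four methods complete the curve between anchors:

- **linear** — a straight chord; area by trapezoid. Optimistic across
  wide tie groups.
- **discrete expectation** — interpolated points at fractional
  true-positive increments x = 0, tp, 2·tp, …, ΔTP on the expectation
  curve, joined by chords.
- **continuous expectation** — the expectation curve itself, integrated
  exactly. With s = ΔFP/ΔTP and left-anchor counts (TP_A, FP_A), the
  expected precision after covering x of the tied positives (all
  orderings of tied entities equally likely) is

      prec(x) = (TP_A + x) / (TP_A + FP_A + (1 + s)·x),  x ∈ [0, ΔTP]

  whose integral over recall has the closed form
  (ΔTP/b + (TP_A − C/b)/b · ln(1 + b·ΔTP/C))/P with b = 1 + s,
  C = TP_A + FP_A (constant prec = ΔTP/(ΔTP+ΔFP) when C = 0).
- **AP (average precision)** — a right-continuous step; the area is
  Σ (R_k − R_{k−1})·P_k over anchors.

An all-tied (no-skill) classifier has continuous-expectation AUPRC
exactly equal to the prevalence P/(P+N). The curve's start at recall 0
is either **derived** (the method's own limit) or forced to the point
(0, 1) — a documented defect of several tools that inflates
chord-integrated areas.

## Worked example

```
$ prc simulate --model discretized --n-pos 30 --n-neg 120 --n-levels 4 --seed 7 --out scores.tsv
wrote 150 rows (P=30, N=120) to scores.tsv

$ prc eval --input scores.tsv --method continuous-exp --out ref.json
auprc=0.331697 auroc=0.696667 baseline=0.200000

$ prc eval --input scores.tsv --profile yardstick-curve --out yard.json
auprc=0.403763 auroc=0.696667 baseline=0.200000

$ prc eval --input scores.tsv --profile scikit-learn-ap --out ap.json
auprc=0.311267 auroc=0.696667 baseline=0.200000
```

One coarsely discretized classifier (four distinct score values, so
large tie groups), three tools, three AUPRCs: the linear-interpolation
profile with a (0, 1) start reports 0.404, the continuous-expectation
reference 0.332, the AP profile 0.311 — a 30% spread on the same
predictions, against a no-skill baseline of 0.200. AUROC is 0.697 under
every profile, which is why the disagreement goes unnoticed when only
ROC is checked. `prc profiles` lists the full emulation catalogue with
each profile's known issues; `prc compare` scores a directory of
submissions under many profiles and enumerates rank flips; `prc curve`
exports the drawn curve's points.

The same operations are available as a library:

```python
from prcmethods import ScoredLabels, build_prc, evaluate_with_profile

data = ScoredLabels(scores=[0.9, 0.8, 0.8, 0.4], labels=[1, 0, 1, 1])
curve = build_prc(data, method="continuous_expectation")
report = evaluate_with_profile(data, "PRROC-continuous")
```

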