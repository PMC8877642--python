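# Methods

## Scope and pipeline

`deidverify` quantifies how well a *masking policy* de-identifies a
seven-field personal-data record, and fits an interpretable surrogate model
of that quantity over the whole policy space. The pipeline is:

1. **generate** — sample a synthetic cohort from fixed demographic tables;
2. **mask** — apply a policy, rendering masked characters as `*`;
3. **score** — compute usability, confidentiality and the final score;
4. **build** — score all 576 policies across a grid of cohort sizes;
5. **train** — tune five tree-based regressors of the score and compare;
6. **explain** — attribute the best model's predictions with TreeSHAP.

## Cohort generator

The demographic tables (packaged in
`src/deidverify/data/demographics_kr2015.yaml`) are percentages from Korean
national statistics: 20 leading family names plus one residual bucket,
11 decade age bands (0–9 … 90–99, >100), 17 provinces/metropolitan cities,
ABO blood-type shares, a 21.5 % smoking rate and five illness labels.
Printed vectors that do not total 100 (blood 99.5, regions 100.2) are
renormalized proportionally at load time; the printed values are retained
on the spec object for reporting. The two extreme consequences: blood type
A samples at 34.17 % rather than the printed 34 %, Seoul at 18.46 % rather
than 18.5 %.

Sampling choices:

* **Names** are always three tokens (family + two given). Given-name
  tokens come from a fixed alphabet of 100 synthetic syllables, because no
  public given-name distribution is modeled; they only need to be
  plausible collision sources for deduplication.
* **Ages** are uniform within their decade band; the open ">100" band is
  realized as uniform on 100–109.
* **Phones** are `010-` plus 8 random digits, pairwise distinct within a
  cohort (rejection sampling; the space of 10⁸ suffixes makes rejection
  negligible at the cohort sizes used).
* **Independence** — fields are sampled independently. Real records
  correlate age with illness, region with name, etc.; none of that is
  emulated. Passing distributional tests therefore validates the marginal
  shares and the scoring machinery, not realism of joint structure.
* **Determinism** — one integer seed; per-cohort streams derive from
  `SeedSequence([seed, cohort_index])`, so cohorts are independent of each
  other but individually reproducible.

## Masking and rendering

Rendering defines group identity for deduplication, so every convention is
fixed:

* Name tokens are masked in the order given₁, given₂, family. The label
  code depends only on *how many* tokens are masked, so the order is purely
  a reproducibility convention; the worked examples in the scoring tables
  mask a given token first, which this order reproduces.
* Ages render as two digits (`07`, `25`); level 1 masks the ones digit
  (`2*`), level 2 both (`**`). Ages 100–109 render by their last two
  digits so the two-digit rule covers every record; no separate century
  marker is kept.
* `partial` phone masking keeps the `010-` prefix and the first random
  digit (`010-7***-****`), following the worked examples. The label-code
  text convention (tens digit = number masked) would suggest the opposite
  split; the examples are treated as authoritative and the convention text
  as an erratum.
* A masked categorical collapses to `*`. Smoking renders `O`/`X` when
  visible.

Masking is idempotent and monotone: raising any field's level never
reveals a character, hence never increases the number of distinct masked
rows (property-tested).

## Scores

* **Usability** is a pure function of the label codes: digit products for
  name/age/phone plus face values for categoricals. The formula gives a
  fully *visible* name or phone (codes 03, 08) a zero contribution — a
  quirk of the published rule that is deliberately preserved, not fixed.
  Its maximum over the policy space is 14, although the banded
  confidentiality score it is summed with reaches 15; the asymmetry is
  likewise preserved.
* **Confidentiality percentage** divides the count of distinct masked
  7-tuples by the *row count* of the original cohort (not by distinct
  original rows — phones make original rows unique anyway).
* **Banding** uses half-open upper-inclusive intervals
  (0,20] → 15 … (60,80] → 6, then (80,99) → 3, [99,100) → 1 and exactly
  100 → 0. The printed band table overlaps at 99/100; the resolution keeps
  "no row collapsed at all" as its own zero-score case and 99–100 % as the
  one-point band. All comparisons are plain float comparisons: the
  percentages are ratios of small integers times 100, so band edges
  (20.0, 99.0, 100.0) are hit exactly when the counts say so.
* **Final score** = usability + band value, range 0–29.

## Regression dataset

Default design: all 576 policies × cohort sizes {100, 500, 1000, 5000} ×
1 replicate = 2304 rows; features are the cohort size plus the seven label
codes kept as plain integers (3, 12, 21, 30 …), the target is the final
score. The sizes span the confidentiality bands at desk scale while
keeping a full build under half a minute; both sizes and replicates are
configurable. Usability is size-invariant, so for a fixed policy the score
varies across sizes only through the band.

## Surrogate models

* Methods: decision tree, random forest, gradient boosting
  (scikit-learn), XGBoost and LightGBM, each behind the
  sklearn-compatible `ScoreSurrogate` estimator.
* Tuning: exhaustive grid search over fixed per-method grids
  (`TUNING_GRIDS`), 5-fold shuffled CV minimizing RMSE, refit on the full
  80 % training split. RMSE alone is the selection metric — a
  single-objective rule avoids an undefined RMSE/R² trade-off, and on a
  common split R² ranks identically to RMSE anyway. Ties break to the
  first configuration in canonical grid order.
* Evaluation: RMSE and R² (computed by the package's own `rmse` /
  `r_squared`, brute-force-verified in tests) on the held-out 20 % split;
  the comparison winner is the lowest test RMSE. Fit times are reported,
  never asserted.
* The split uses scikit-learn's shuffle split (2304 rows → 1843/461).

On this dataset design every feature vector is unique, while the grids'
minimum-leaf constraints (e.g. LightGBM `min_child_samples = 5`) force
leaves to pool several policies; the surrogate therefore smooths a
spiky, deterministic target and its held-out R² plateaus around 0.97
(measured by the acceptance script, not asserted as a test tolerance).
Designs with replicated rows would allow finer fits; the default is kept
at one replicate for a compact, fully enumerable dataset.

## TreeSHAP

Attributions use the exact path-dependent TreeSHAP formulation
(conditional expectations estimated from the tree's own cover weights).
LightGBM and XGBoost models are attributed with their built-in
`pred_contrib` implementations; scikit-learn trees and ensembles go
through the package's own implementation in `treeshap.py`, which is
verified in tests against a brute-force Shapley enumeration over all 2^p
coalitions (p ≤ 4) and satisfies local accuracy
(base value + Σ attributions = prediction, asserted at 1e−6 on every
evaluated instance). Attributions are computed on the test split; the
importance ranking orders features by mean |SHAP| with alphabetical
tie-break, and the direction summary reports the sign of the Spearman
correlation between feature value and attribution (null for constant
features).

Path-dependent attributions are zero for features the ensemble never
splits on; symmetry between duplicated features holds at the ensemble
level (tested on hand-built stumps), not within a single tree that uses
only one copy.

## Problem sizes and runtimes

Chosen as desk-scale defaults: distributional checks use one 200,000-row
cohort (a few seconds to generate); deduplication oracle checks use
cohorts ≤ 200 where the O(n²) oracle is cheap; the full five-method grid
search on the 2304-row dataset takes a few minutes on one CPU, and the
acceptance script (generator shares + LightGBM tuning only) under two.

## Known limitations

* Field independence and token-level synthetic given names: validated
  behavior concerns the scoring pipeline, not demographic realism.
* The usability weights and the equal summing of usability and the
  confidentiality band are conventions of the scoring rule, not calibrated
  quantities.
* Only masking is modeled; generalization hierarchies, suppression,
  noise addition and formal models (k-anonymity, differential privacy) are
  out of scope.
* The surrogate's accuracy ceiling is tied to the dataset design (unique
  feature vectors vs. minimum-leaf constraints), as noted above.
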