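# deidverify

Verification of masking-based de-identification policies for personal
health records, built around a privacy–utility score and an interpretable
tree-ensemble surrogate of that score.

## The problem

Pseudonymized (de-identified) personal data can legally be reused without
consent in many jurisdictions — but only if the de-identification was done
properly. Over-masking destroys analytic value; under-masking leaves
individuals identifiable. `deidverify` implements a quantitative
verification framework for the most common de-identification operator,
character masking, on records with seven fields: name, age, phone number,
residential area, illness, blood type and smoking status.

The package is aimed at privacy engineers and health-informatics
researchers who need to (a) score a concrete masking policy against a
dataset, and (b) understand *which* masking choices drive that score.

## The model

**Synthetic cohorts.** Because real personal data cannot be used for this
purpose, cohorts are generated from published Korean national statistics:
21 family-name frequencies (Kim 21.56 %, Lee 14.74 %, …), 11 decade age
bands, 17 regional population shares, ABO blood-type shares
(A 34 / B 26.6 / O 27.5 / AB 11.4, renormalized), a 21.5 % smoking rate,
five uniformly distributed illnesses, and unique random `010-dddd-dddd`
phone numbers. Fields are sampled independently; everything is reproducible
from one integer seed.

**Masking policies and label codes.** A policy fixes per field how much is
masked: 0–3 name tokens, 0–2 age digits, phone `none`/`partial`/`full`,
and a keep/mask bit for each categorical field. Each level is encoded as an
integer label whose tens digit counts masked characters and ones digit
counts visible ones (name 03/12/21/30, age 02/11/20, phone 08/17/80;
categoricals 1 = kept, 0 = masked).

**Scores.** For label codes ℓ over the seven fields:

- *usability* U = Σ (tens(ℓ) × ones(ℓ)) over name/age/phone
  + Σ ℓ over the categoricals   (range 0–14),
- *confidentiality* C% = (#distinct masked rows / n) × 100, banded in
  steps of 3: (0,20] → 15, (20,40] → 12, (40,60] → 9, (60,80] → 6,
  (80,99) → 3, [99,100) → 1, exactly 100 → 0,
- *final score* = U + band(C%).

**Surrogate and interpretation.** Scoring every policy in the
4×3×3×2⁴ = 576-policy space against cohorts of sizes
{100, 500, 1000, 5000} yields a 2304-row regression dataset
(features: cohort size + 7 label codes; target: final score). Five
tree-based regressors (decision tree, random forest, GBM, XGBoost,
LightGBM) are tuned by exhaustive grid search with 5-fold CV minimizing
RMSE, compared on a held-out 20 % split by RMSE/R², and the winner is
interpreted with exact TreeSHAP attributions (mean-|SHAP| importance
ranking and per-feature direction-of-effect trends).

## Worked example

```python
import deidverify as dv

cohort = dv.generate_cohort(1000, seed=42)
policy = dv.MaskingPolicy(name_level=1, age_level=1,
                          phone_level="partial", illness_mask=True)
print(dv.label_policy(policy))
print(dv.score_policy(cohort, policy))
```

prints

```
LabeledPolicy(name_label=12, age_label=11, phone_label=17, blood_label=1,
              region_label=1, illness_label=0, smoking_label=1)
ScoreBreakdown(usability=13, confidentiality_pct=99.9,
               confidentiality_value=1, final_score=14)
```

Usability 13 = (1×2) + (1×1) + (1×7) + 1 + 1 + 0 + 1: the policy keeps most
analytic value. But with one phone digit still visible, 999 of the 1000
masked rows remain distinct — 99.9 % confidentiality percentage, band score
1 — so the policy barely de-identifies at all and the final score is a
modest 14. Masking more aggressively changes the balance:

```python
strong = dv.MaskingPolicy(name_level=2, age_level=2, phone_level="full",
                          blood_mask=True, illness_mask=True)
print(dv.score_policy(cohort, strong))
# ScoreBreakdown(usability=4, confidentiality_pct=30.4,
#                confidentiality_value=12, final_score=16)
```

The same pipeline is available from the shell:

```bash
deid-verify generate --n 1000 --seed 42 --out cohort.csv
deid-verify build --sizes 100,500,1000,5000 --seed 42 --out dataset.csv
deid-verify train --data dataset.csv --seed 42 --out report/
deid-verify explain --data dataset.csv --seed 42 --out shap/
deid-verify run --out full-run/        # all stages + manifest
```

On the default dataset the grid-searched LightGBM model wins the
comparison (held-out RMSE ≈ 1.01, R² ≈ 0.97), and its TreeSHAP ranking
puts the phone-number label first by a wide margin — phone digits are
near-unique, so their masking level dominates group collapse and hence the
score.

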