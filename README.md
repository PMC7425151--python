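# orthoclaims

Identify elective orthopedic surgeries — and *why* they were performed —
from administrative claims.

Research on shared decision-making (SDM) needs to find patients who had one
of a handful of preference-sensitive operations for a preference-sensitive
reason: knee arthroplasty for knee osteoarthritis (KOA), hip arthroplasty
for hip osteoarthritis (HOA), and lumbar spinal surgery for spinal stenosis
(SpS) or herniated disc (HD). Billing data records *what* was done (CPT
procedure codes) and *which diagnoses* were present (ICD-10-CM), but not
which diagnosis was the primary indication — a hip replaced for a femoral
neck fracture is not an SDM-relevant case, even if osteoarthritis codes are
also on the chart. `orthoclaims` implements a validated two-step
rule engine over a 90-day pre-surgical code window, plus the
diagnostic-accuracy machinery used to validate it and a synthetic cohort
simulator so the whole pipeline runs without access to patient data.

## The algorithm

For each surgical case, using all codes billed in the 90 calendar days up
to and including the surgery date, and applying each combination's rules
only to cases from its own surgeon-specialty panel (spine vs hip/knee):

1. **Inclusion.** A combination is flagged when the window contains at
   least one of its inclusion CPT codes *and* at least one of its inclusion
   ICD-10 codes. CPT-only, ICD-only, or neither ⇒ the case is "other".
   A spine case flagged for both SpS and HD is resolved by age: **≥ 50
   years ⇒ SpS, < 50 ⇒ HD**.
2. **Exclusion.** If any window ICD-10 code matches the combination's
   exclusion list (fracture, neoplasm, infection, and other markers of
   non-elective surgery; a trailing `*` matches every child in the ICD-10
   hierarchy), the condition is demoted to a *secondary* indication and the
   primary indication is "other"; otherwise the condition is the primary
   indication.

Validation against gold-standard chart review uses, per combination and
classification level (indication / primary indication),

```
Se = TP/(TP+FN),   Sp = TN/(TN+FP)
```

with exact Clopper–Pearson 95% intervals (beta-quantile inversion of the
binomial tails), predictive values at an arbitrary prevalence *p*

```
PPV(p) = Se·p / (Se·p + (1−Sp)(1−p)),   NPV(p) = Sp(1−p) / (Sp(1−p) + (1−Se)p)
```

and unweighted Cohen's kappa for inter-rater agreement.

## Worked example

```python
import orthoclaims as oc
from orthoclaims.claims_io import filter_eligible, window_events
from orthoclaims.synth import SimulationConfig, generate_cohort

book = oc.default_codebook()                      # the packaged code lists
ds = generate_cohort(SimulationConfig(seed=7))    # 790-case synthetic cohort
cases, _ = filter_eligible(ds.cases)              # age >= 21 spine, >= 40 hip/knee
cases = [window_events(c, ds.claims) for c in cases]
preds = oc.classify_cohort(cases, book)

results = oc.AlgorithmValidation(preds, ds.gold).fit()
print(results.summary())
```

```
level               combination  sensitivity          specificity
---------------------------------------------------------------------------
indication          SPS          0.90 (0.83, 0.94)    0.99 (0.97, 1.00)
indication          HD           0.78 (0.65, 0.89)    0.99 (0.97, 1.00)
indication          KOA          0.94 (0.88, 0.98)    1.00 (0.99, 1.00)
indication          HOA          0.90 (0.84, 0.94)    1.00 (0.99, 1.00)
primary_indication  SPS          0.86 (0.78, 0.92)    0.99 (0.97, 1.00)
primary_indication  HD           0.80 (0.65, 0.90)    0.99 (0.97, 1.00)
primary_indication  KOA          0.90 (0.83, 0.95)    1.00 (0.99, 1.00)
primary_indication  HOA          0.73 (0.65, 0.80)    1.00 (0.99, 1.00)
```

Each row is a sensitivity or specificity with its exact 95% interval. The
two levels differ because the exclusion step only affects *primary*
indication calls: here the HOA primary-level sensitivity drops to 0.73
because simulated hip cases carrying an osteonecrosis code are demoted even
when osteoarthritis was the true primary indication — the same failure mode
the audit table tags:

```python
results.misclassification_report().cause.value_counts().head(3)
# missing_cpt                20
# exclusion_demotion:M87*    16
# exclusion_demotion:R15*    14
```

The same pipeline is available as a CLI:

```sh
orthoclaims simulate --out data/ --seed 17
orthoclaims classify --claims data/claims.csv --cases data/cases.csv --out run/
orthoclaims validate --predictions run/classifications.csv --gold data/gold.csv --out run/
orthoclaims pv --sens 0.92 --spec 0.99 --prior-grid 0:1:0.01 --mark 0.27 --out pv.csv
orthoclaims codebook lint my_codebook.yaml
```

## Layout

- `orthoclaims.codebook` — code normalization, hierarchy (prefix) matching,
  the YAML codebook format, and the packaged default lists
- `orthoclaims.claims_io` — claims/case/gold tables, the 90-day window,
  eligibility filters
- `orthoclaims.classifier` — the two-step rule engine
- `orthoclaims.validation` — `AlgorithmValidation` → `ValidationResults`
  (confusion counts, Se/Sp with exact CIs, PPV/NPV curves, kappa, audit)
- `orthoclaims.synth` — archetype-based synthetic cohort generator
- `orthoclaims.cli` — `classify`, `validate`, `pv`, `simulate`,
  `codebook lint`

See `docs/methods.md` for the modelling choices, simulator assumptions, and
known limitations.
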