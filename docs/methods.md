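# Methods

## The classification model

`orthoclaims` classifies surgical cases, not patients: the unit of analysis
is one operation by a spine or hip/knee surgeon, and the feature set is the
bag of ICD-10-CM and CPT codes billed for that patient in a closed window
of 90 calendar days ending on (and including) the surgery date. The engine
is deliberately a deterministic rule system rather than a fitted model —
its value is auditability: every call can be traced to the specific codes
and patterns that produced it.

Assumptions worth stating explicitly:

- **ICD-10 hierarchy = string prefix.** After uppercasing and removing the
  dot, a code's ancestors are exactly its string prefixes, so a
  hierarchical ("`*`") pattern is a `startswith` test on normalized
  strings. CPT has no such structure; CPT codes match exactly.
- **Inclusion lists match exactly by default.** Only asterisked entries of
  the exclusion lists carry hierarchy semantics in the shipped codebook.
  Some inclusion diagnoses do have children in ICD-10-CM, so the loader
  exposes `inclusion_hierarchy: true` (config key or
  `load_codebook(..., inclusion_hierarchy=True)`) to extend prefix
  matching to inclusion lists; the default is off and the choice is
  surfaced rather than guessed.
- **The window is 90 days, both endpoints counted.** "90 days before
  surgery, inclusive of the surgery date" is read as the closed span
  `[surgery − 89, surgery]`, i.e. exactly 90 calendar days. The alternative
  reading (91 days, `[surgery − 90, surgery]`) is one parameter away
  (`window_days=91`).
- **Panel restriction.** Each combination's rules are applied only to
  cases from its own surgeon panel; this mirrors the validated setting.
  `panel_restriction=False` evaluates all four rule sets on every case —
  useful for data without surgeon-specialty breakdowns, where it tends to
  inflate specificity (off-panel cases almost never carry on-panel
  procedure codes) without changing sensitivity.
- **Order of operations.** Inclusion matching → spine age tie-break →
  exclusion screening, in that fixed order. With the shipped codebook the
  order of tie-break and exclusion is immaterial because the two spine
  exclusion lists are identical, but the engine fixes the sequence so that
  custom codebooks with divergent spine exclusion lists behave predictably.
- **Undefined case.** A case whose window satisfies two same-panel
  combinations as primary (hip *and* knee codes in one window) has no
  defined answer in the validated setting; the engine labels it
  `ambiguous` and logs a warning instead of silently picking one.

Key parameters: `spine_age_threshold_years` (default 50; ≥ threshold ⇒
SpS when dual-coded), `window_days` (default 90), eligibility floors
(21 years for spine, 40 for hip/knee cases), `alpha` for intervals
(default 0.05).

## Validation statistics

Sensitivity and specificity are binomial proportions over the
panel-restricted gold positives/negatives; their intervals are exact
Clopper–Pearson bounds computed from beta quantiles,
`BetaInv(α/2; x, n−x+1)` and `BetaInv(1−α/2; x+1, n−x)`, with the
conventional endpoints at x = 0 and x = n. The test suite checks this
implementation against two independent routes: direct bisection on the
binomial tail probabilities (agreement to 1e−8 for all x ≤ n ≤ 60) and
statsmodels' beta-method interval. Empirical coverage is verified to be at
least the nominal 95% (exact intervals are conservative).

Predictive values are pure functions of (Se, Sp, p) via Bayes' rule and are
reported as `nan` when the denominator vanishes (e.g. PPV at p = 0 with
Sp = 1) — an undefined value is never silently reported as 0. PPV is
nondecreasing and NPV nonincreasing in p; both properties are tested, and
the formulas are cross-checked against Monte-Carlo frequencies in simulated
labeled populations (agreement within 3 standard errors).

Cohen's kappa is the unweighted `(po − pe)/(1 − pe)`; `po = 1` returns 1
(for a square count table, `pe = 1` forces `po = 1`, so the undefined
branch is unreachable in practice but guarded anyway).

A zero denominator (no gold positives for a combination in a small cohort)
raises an explicit undefined-metric error at the function level; the fitted
`ValidationResults` records such metrics as missing and prints them as
`undefined` in the summary.

The estimation surface follows the Model/Results convention
(`AlgorithmValidation(...).fit() → ValidationResults`) because validation
*is* a statistical estimation step; the rule engine itself is not a fitted
model and keeps a plain functional surface.

## The misclassification audit

Primary-level errors are tagged with the cause recoverable from claims
alone: `exclusion_demotion:<patterns>`, `tie_break_override`,
`missing_cpt`, `missing_icd`, else `unresolved` (requires chart review).
These tags reproduce, on synthetic data, the dominant documented failure
modes of this class of algorithm: elective hip cases demoted by
non-site-specific osteonecrosis/fracture codes, spine cases flipped between
stenosis and herniated disc by the age rule, and procedures whose billing
codes never reached the extract.

## The synthetic cohort generator

The generator's defaults describe a cohort like the validation study's:
790 cases over a two-month enrollment window, with an archetype mix chosen
to match the study's observed distribution of indications (≈17% HOA, 15%
KOA, 17% SpS with a small dual-coded fraction, 7% HD, and 44% other
procedures performed by the same panels). Eleven archetypes cover clean
elective cases per combination, fracture/neoplasm-driven look-alikes,
osteonecrosis-coded elective hips, dual-coded spine cases with either gold
truth, and off-target procedures (cervical fusion, knee arthroscopy).

Corruption rates were set from the relative frequency of the documented
failure modes in the study's misclassification audit, as this package's own
defaults: `p_drop_cpt = 0.06` (missing procedure billing codes caused
roughly 5–9% of false negatives per combination), `p_drop_icd = 0.02`,
`p_add_exclusion = 0.05` (stray exclusion diagnoses), and
`p_dual_spine_coding = 0.10` (SpS↔HD cross-coding, the dominant spine
error). Ages are drawn uniformly on per-archetype ranges bracketing the
study's reported mean ages; no attempt is made to match the means exactly.
All randomness flows through one `numpy` generator seeded from the config;
identical configs produce byte-identical output files.

Each case's archetype and corruption draws are recorded in `truth.csv`
together with the label the engine *should* produce
(`synth.expected_label`), computed declaratively from the recipe — this is
the oracle used for full-cohort equivalence tests, and it shares no code
with the classifier.

What the simulator does **not** emulate: realistic visit/billing timing
(events sit at fixed offsets), surgeon identity, comorbidity breadth, code
co-occurrence structure, or free text. Passing tests therefore demonstrate
that the engine implements its rules exactly and that the validation
statistics behave as designed — not that the shipped code lists achieve any
particular accuracy on another institution's real claims.

## Numerical and testing choices

- Test problem sizes were chosen to keep the full suite under a minute
  while leaving no property thinly sampled: oracle-equivalence cohorts of
  500 cases × 3 seeds, coverage simulations of 5,000 replicates per (n, p),
  recovery checks of 20 seeded replicates of 400 cases, Monte-Carlo
  predictive-value populations of 1.5–2 × 10⁵.
- The planted-rate recovery check uses two constructions with analytically
  known operating characteristics: sensitivity 1 − p_drop_cpt on a pure
  knee cohort, and specificity 1 − (share of dual-coded HD cases × P(age ≥
  50)) on a spine mix where the age tie-break is the only error source.
- Hypothesis runs derandomized so failures are reproducible.
- Table parsing treats all columns as strings and never coerces: malformed
  rows are skipped and itemized in a parse report, because administrative
  extracts are dirty and silent row loss would bias downstream counts.

## Known limitations

- The shipped code lists are those of the validated setting; other
  institutions' coding practice may require edits (the codebook is a YAML
  document, linted by `orthoclaims codebook lint`).
- Printed specificities of the original validation depend on the exact
  surgeon-panel composition of its sample and are not reconstructible from
  published aggregates; the acceptance tooling therefore reproduces the
  primary-indication sensitivities and interval bounds, and validates
  specificity behavior on synthetic cohorts with planted rates instead.
- The SpS/HD age tie-break is a crude instrument — dual-coded cases are
  intrinsically hard to separate in claims, and the simulator makes that
  error mode visible rather than solving it.
- One claim row = one (patient, code, date); multi-surgery episodes are not
  linked, and a patient with two operations inside 90 days would
  contribute overlapping windows.
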