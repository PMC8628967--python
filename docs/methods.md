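# Methods

## Cohort model and temporal resolution

The cohort is four tables: patient baseline attributes, interval-coded
prescriptions, date-stamped coded comorbidities, and one clinical snapshot
per follow-up visit. Visits are indexed by month offset from baseline
(default grid 0, 6, …, 36) and mapped to calendar dates through the
patient's baseline date; dates are ISO-8601 only, so I/O round-trips
bit-exactly.

A prescription is *active* on a date if `start_date <= date` and the end
date is absent (ongoing) or `>= date` — a closed, end-inclusive interval.
This is the natural reading of interval-coded prescription data; no
half-open convention is assumed. The state a rule reads at a visit bundles
the active prescriptions, every comorbidity with onset at or before the
visit date (with months elapsed since onset, for recency windows), and the
most recent snapshot at or before the visit. A missing snapshot is a marked
state, not an error.

Free-text comorbidity coding is human work done upstream; the loader
accepts a controlled vocabulary (strict mode, default) or passes unknown
labels through (lenient mode). Prescriptions must carry full 7-character
level-5 ATC codes; rule files may use class prefixes.

## Rule representation and evaluation

One rule encodes one explicit criterion: a source tool (EU(7)-PIM, STOPP,
START, AMI, withdrawal, contraindication), a kind (`list_match`,
`conditional`, `omission`, `interaction`), a trigger predicate, and a
`dedup_key` naming the *semantic* criterion so that the same clinical
content encoded by two tools can be recognized as a strict duplicate.
Predicates are finite boolean trees over typed atoms (drug activity with
optional dose/duration constraints, drug absence, co-prescription counts,
condition presence/absence with optional recency windows, clinical-measure
thresholds, performed procedures) combined with `all`/`any`/`not`.
Standalone `dose`/`duration` atoms inside an `all` narrow the prescriptions
matched by the drug atoms before them; this keeps criteria like "NSAID for
three months or longer" writable without nesting.

Missing clinical data make a criterion *uncodable*, never positive:
evaluation is three-valued in the Kleene sense. A measure atom on a missing
value is Unknown; `False AND Unknown` is False (the rule simply cannot
fire), while `True AND Unknown` abstains, and the abstention is logged with
its reason. Missing data can therefore only lower sensitivity, never create
false positives.

Emission multiplicity follows the kind: list/conditional rules emit one
MRNC per matching active prescription (one per distinct ATC code — two
simultaneous orders of the same substance are one noncompliance); omission
rules emit at most one MRNC per patient-visit with an empty trigger set
(the noncompliance is a missing treatment, so it attaches to the visit, not
to a drug line); interaction rules emit one MRNC per unordered co-active
pair. Deduplication keeps at most one MRNC per (patient, visit, dedup_key,
trigger drugs), retaining the tool highest in STOPP > START > EU(7)-PIM >
AMI > WITHDRAWAL > CONTRAINDICATION order — the retained record's tool
affects provenance display only. Per-tool prevalence summaries use the raw
stream (so tools can be compared before duplicates collapse); PIP flags and
MRNC-count histograms use the deduplicated stream, and both counts are
exported.

### The demonstration rulebank

Shipping the complete licensed criterion texts (282 EU(7)-PIM entries, 47
coded STOPP and 24 coded START criteria, thousands of SmPC contraindication
pairs) is out of scope; the packaged bank is a curated demonstration that
exercises every atom type and encodes the documented coding decisions:
STOPP A1 restricted to its two codable sub-criteria (aspirin/statin in
primary cardiovascular prevention, with aspirin treated as antiplatelet at
<= 325 mg/day; proton pump inhibitor without oesogastric damage in the last
12 months — the recency window is a configurable default, as no canonical
value exists); STOPP B6 as loop diuretic + hypertension + no heart/liver
failure or nephrotic/renal syndrome + no other concomitant antihypertensive
(antihypertensive set C02, C03 minus loop diuretics, C07, C08, C09 —
configurable); START G1/G2 merged, considering only whether prostatectomy
was *performed*. STOPP K1/K2/K4 (too broad to be clinically actionable,
redundant with more specific criteria) and START C3 (no longer recommended
in France) are deliberately absent. Long-half-life benzodiazepines appear
both as EU(7)-PIM entries and as an AMI indicator under a shared dedup key,
so strict-duplicate collapsing is exercised by the packaged content itself.

## Charlson index

Plain 1987 weights over distinct conditions, packaged as a data file
(weight-1: infarction, heart failure, peripheral vascular disease,
stroke/TIA, COPD, ulcer, diabetes, dementia; weight-2: severe CKD, cancer;
weight-3: liver failure; weight-6: metastatic cancer, AIDS; hypertension
0). The age-adjusted variant is *not* used: in a cohort aged >= 70 it would
add at least 3 points to every patient, making the dominant score-0 stratum
impossible. Scores are categorized 0 / 1 / >= 2.

## Synthetic cohorts and planted truth

The generator's defaults are the study conditions of the reference
population: 1,525 patients, 7 six-monthly visits, 64 % female, age groups
0.50/0.32/0.18, education 0.22/0.34/0.15/0.29, four ~equal intervention
arms, comorbidity prevalences (hypertension 0.66, MI 0.06, heart failure
0.04, PVD 0.03, stroke/TIA 0.03, COPD 0.03, ulcer 0.04, diabetes 0.01,
severe CKD 0.01, cancer 0.01 — independent draws, which imply ~78 % at
Charlson 0), medication-count categories 0.53/0.39/0.08, frailty missing in
5 % of visits and education in 2 % of patients. Dropout defaults to 0.

Ground truth is exact *by construction*, never by re-detection. A planted
trigger is a curated bundle (drugs in a short window covering one visit,
required/forbidden conditions, a forced orthostatic drop where the
criterion needs one) whose fired rule set is known; filler drugs come from
a neutral pool verified at generator start to match no rule atom, so
non-planted visits fire nothing. Omission criteria need special care on a
longitudinal grid: the planted condition (prostatism, osteoporosis) onsets
one month before its visit and the omitted drug class is started one month
after, so the omission fires at exactly one visit. Medication counts are
topped up with fillers to each patient's target count, so planting never
moves a patient across a polypharmacy category boundary.

In **outcome-model mode** the latent PIP status comes from the
random-intercept logistic model; the default planted effect sizes are the
reference study's adjusted odds ratios (age 75–79: 2.75, >= 80: 5.36;
polypharmacy: 26.64, hyperpolypharmacy: 662.16; Charlson 1: 10.89, >= 2:
21.93; sigma_u = 1, intercept set for ~15 % prevalence in the reference
stratum), and a `null()` preset zeroes every effect for calibration runs.
In **tool-prevalence mode** each tool plants a tool-pure construct at
baseline with a configured probability, so per-tool patient prevalences are
exact Bernoulli draws. The generator does not model incident comorbidities
(all sampled conditions onset before baseline), drug co-occurrence
correlations, dose titration, or realistic persistence of therapy (filler
windows cover single visits); passing tests therefore demonstrate the
correctness of the detection and inference machinery under known
conditions, not the clinical realism of any prevalence estimate.

## Statistics

Baseline comparisons: Pearson χ² *without* continuity correction, switching
to Fisher's exact test when any expected count `E_ij = R_i C_j / N` is
below 5 and the table is 2×2 (below 5 on a larger table falls back to χ²
with a warning). The two-sided Fisher p follows the minimum-likelihood
rule — the sum of probabilities of all fixed-margin tables whose point
hypergeometric probability does not exceed the observed one. Both choices
were fixed by validating against the printed reference table: with a
continuity correction, or with tail-doubling Fisher, the printed p-values
(0.688 gender, 0.090 peptic ulcer, 0.145 diabetes, 0.223 cancer) are not
reproduced. The test suite checks χ² against Monte-Carlo sampling of the
exact fixed-margin null (multivariate hypergeometric draws); those checks
use large, balanced tables (n ≈ 10⁵) because that is the regime where the
asymptotic reference distribution is meant to hold.

Missing covariates above a 1 % threshold are imputed by chained equations
with multinomial-logistic conditionals (draws from predictive
probabilities, 5 sweeps, m = 5 by default); variables at or below the
threshold are left untouched. Estimates over the m completed datasets are
pooled by Rubin's rules with the Rubin degrees of freedom; with m = 1 the
pooled result equals the single fit.

The mixed logistic model integrates the patient random intercept by
Gauss–Hermite quadrature (15 nodes — one-dimensional, so nearly exact) and
maximizes the marginal likelihood with L-BFGS-B using an analytic gradient;
standard errors come from the inverse observed information
(finite-difference Jacobian of the gradient), and odds ratios carry Wald
95 % intervals. The implementation agrees with R `lme4::glmer`
(`nAGQ = 15`) to ~2 decimal places on shared fixtures, and `glmer` serves
as an independent oracle in the test suite. Complete separation (outcome
constant overall or within a dummy level) is detected before fitting and
returned as a flagged, estimate-free result; empty dummy columns are
dropped so the information matrix stays invertible, and non-convergence is
always flagged, never silent.

## Numerical and design notes

- Dose constraints require a matching unit and a recorded dose; an unknown
  dose never satisfies a dose-qualified atom (conservative direction).
- Engine output order is fixed (patient, visit, rule, drugs), so identical
  inputs give byte-identical artifacts; every CLI artifact directory embeds
  the rulebank version, seed and configuration.
- Elapsed months use the mean month length (30.4375 days); recency windows
  are compared inclusively.
- Calibration experiments in the acceptance suite use 50 replicates of
  1,000 patients × 7 visits; detection-correctness experiments use 200
  patients against the exact planted ledger and 100 small random cohorts
  against an independent brute-force evaluator.

## Known limitations

The packaged rulebank is a demonstration subset, so prevalence outputs on
real data reflect only the encoded criteria. The generator's simplifying
assumptions (no incident comorbidity, independent comorbidities, per-visit
drug windows) are listed above. The mixed model fits a single random
intercept only — no random slopes — matching its intended use as a
construct-validity check, and Wald intervals are first-order asymptotic.
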