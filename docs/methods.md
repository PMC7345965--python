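# Methods

## Problem setting

A targeted assay quantifies 35 amino acids and derivatives in 24-hour
urine. Cases are recurrent kidney-stone formers (SF, coded 1), controls
are healthy subjects (CNT, coded 0); the default cohort size is 15 SF +
12 CNT, matching the study population this package models. The pipeline
answers three questions: can the classes be separated (and how well, on
held-out samples), which analytes drive the separation, and could the
apparent separation have arisen by chance.

## PLS-DA (NIPALS PLS1)

The classifier regresses the centred 0/1 class vector on the scaled
concentration matrix. For each latent variable on the deflated (X, y):

    w_a ∝ X'y (unit norm),  t_a = X w_a,
    p_a = X't_a/(t_a't_a),  q_a = y't_a/(t_a't_a),
    X ← X − t_a p_a',       y ← y − q_a t_a.

Coefficients are accumulated through r_a = w_a − Σ_{b<a}(p_b'w_a) r_b so a
single fit yields the prediction path for every truncated model 1..A;
the full-model B equals W(P'W)⁻¹q. Predictions are ŷ = ȳ + X_scaled·B and
the decision rule is SF iff ŷ > 0.5, with the tie (ŷ = 0.5) going to the
control class. NIPALS PLS1 was chosen over SIMPLS or a two-column dummy
coding because binary PLS2 is equivalent and the PLS1 recursion is directly
auditable against textbook pseudocode; agreement with an independent PLS
implementation is a test, not a dependency. There is no random
initialisation: identical inputs give bit-identical models.

Checked identities: unit-norm orthonormal weights, mutually orthogonal
scores, PLS at full rank = least-squares fit (1e-8), single-predictor PLS
= simple regression, mean(VIP²) = 1.

## Scaling

Autoscaling (mean-centre, unit variance, SD with n−1) is the default: the
panel spans two orders of magnitude of abundance and an unscaled model
would be dominated by serine, glycine and histidine. `pareto`, `center`
and `none` are available through the `scaling` option. Scaling parameters
are always fitted on the training rows of the current partition only —
this is the leakage boundary for every loop, inner and outer. Columns that
are constant in training scale to zero (rather than erroring), so
label-permutation replicates never crash on a degenerate fold.

## Double cross-validation

Defaults: 5 outer folds, 5 inner folds, 20 repetitions, up to 10 latent
variables. With 27 samples each outer fold holds 5–6 of them, and 20
repetitions give a stable SEM; all four numbers are configurable.
Stratified folds deal each class round-robin after shuffling; a class
smaller than the fold count reduces the fold count (warning), a class with
fewer than 2 members is an error naming the class.

Per outer fold, the inner CV evaluates every LV count on pooled inner
predictions and picks the minimum-NMC count, ties to fewer LVs
(parsimony). The outer model is refit at that count and scores only its
held-out fold, so each sample is predicted exactly once per repetition.
Reported rates are repetition-averaged (mean ± SEM, SEM = SD/√n_reps);
per-sample pooling would be the alternative reading and is recoverable
from the stored per-repetition score matrix. The final interpretable
model — used for the score plot export and VIP — is refit on all samples
at the modal chosen LV count across all outer fits.

## Biomarker selection

VIP comes from the final all-data model; the rank product is computed
across the outer-fold submodels of the DCV, ranking analytes within each
submodel by |regression coefficient| (rank 1 = largest, mid-ranks for
ties) and taking the geometric mean. Feeding RP with resampled submodel
coefficients while VIP uses the single final model makes the two selectors
genuinely complementary: one is model-based, the other measures stability
under resampling. The consensus set is the intersection of the top-k of
both rankings (k = 9 by default), with a deterministic alphabetical
tie-break.

A caveat established by simulation (see the selection test suite): at
n = 27 with 26 null analytes, the largest chance class-correlation among
the nulls is regularly comparable to the sample correlation of the weakest
true discriminant, so exact recovery of all nine planted analytes happens
in only roughly 40% of cohort realizations; at least seven of nine are
recovered essentially always, and the two selectors' top-9 sets overlap by
at least eight. Consensus selection at this cohort size identifies a core
signature reliably but its tail is unstable — a property of the design,
not of the algorithm.

## Permutation significance

Each permutation shuffles the labels only (X untouched, preserving the
analyte correlation structure) and re-runs one complete DCV pass —
scaling, LV selection and outer prediction all inside — then NMC, AUROC
(Mann-Whitney rank formulation, ties 0.5) and DQ2 are computed on the
pooled outer predictions. One pass per permutation (rather than the full
20 repetitions) keeps 1000 permutations at ~20 s on one CPU; the observed
statistics use the identical single-pass computation so observed and null
values are exchangeable. DQ2 zeroes the residual of any prediction that
overshoots its own class label (ŷ > 1 for a case, ŷ < 0 for a control),
hence DQ2 ≥ Q2 always. P-values use the add-one estimator, which cannot
return zero and is uniform under the null (verified over 50 no-signal
replicates).

## Univariate companion table

Default protocol: two-sided Mann-Whitney U for every analyte (exact
enumeration when combined n ≤ 12 and tie-free, else the tie-corrected
normal approximation). An optional normality-gated mode applies
Shapiro-Wilk per group (α = 0.05) and uses Welch's t-test when both groups
pass. Raw p-values are the primary output; a Benjamini-Hochberg column is
appended as a clearly-labelled supplementary extension. A
summary-statistic Welch test (`welch_t_from_summary`) is provided for
checking published group summaries without raw data.

## Synthetic cohort generator

The generator is parameterized, by default, from the published group
summaries: nine discriminant analytes with their printed CNT/SF mean ± SD
(all lower in SF), and 26 null analytes at physiologically plausible
urinary levels (identical in both groups, CV 35%) since their per-subject
values were never published. Units are treated as abstract concentration
units as printed (the source table does not state whether values are
creatinine-normalized).

Distributions: lognormal by default — closed-form moment matching
(σ² = ln(1+s²/m²), µ = ln m − σ²/2) and guaranteed positivity — or a
zero-truncated normal whose parent parameters are solved numerically
(1-D in α = −µ/σ, where the CV is monotone). A zero-truncated normal has
CV strictly below 1, so a target with SD ≥ mean (one SF analyte in the
default panel) is capped just below the attainable supremum: its mean is
matched exactly and its realized SD falls slightly short. SD = 0 produces
a constant column.

Analytes are independent by default; an equicorrelation parameter ρ on the
latent Gaussian scale is available because the classifier is motivated by
correlated predictors. Each (analyte, group) pair has its own RNG stream
derived from the root seed, so extending the panel never perturbs existing
columns.

What the generator does **not** emulate: instrument drift, carryover,
LOD censoring, creatinine normalization, realistic inter-analyte
correlation structure (pathway co-regulation), or covariate confounding
(the real cases and controls differed in age and BMI). Passing tests
therefore demonstrate the statistical machinery is correct and calibrated,
not that real cohorts of this size will reach the same rates: the
synthetic effect sizes are taken at face value from the summary table and
are large, which is why synthetic classification rates (high 80s to high
90s %) exceed the real-data rates.

## Numerical choices

- NIPALS stops early (with a warning) when ‖X'y‖ or t't falls below
  1e-12 of the initial matrix scale; requesting more LVs than
  min(n−1, p) truncates with a warning.
- Decision threshold fixed at 0.5 for 0/1 coding; exact ties → control.
- Inner folds whose training set runs out of rank reuse the deepest
  extractable model for the remaining LV counts.
- Empirical p-values count null values equal to the observed statistic as
  extreme (conservative).
- Cohort CSVs are written with %.17g and read with round-trip float
  parsing, so write→read is exact.
- Root seeds fan out to stages (cohort/DCV/permutation) through fixed
  SeedSequence offsets; derived seeds stay below 2³¹.

## Limitations

- With ~27 samples, all reported rates have wide sampling variability
  across cohort draws; the SEM over repetitions quantifies fold-assignment
  noise only, not cohort-level uncertainty.
- The selection tail instability described above means top-k membership
  beyond the strongest effects should not be over-interpreted.
- The permutation test evaluates the pipeline exactly as configured; it
  does not protect against choices made outside it (e.g. trying several
  scaling modes and keeping the best).
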