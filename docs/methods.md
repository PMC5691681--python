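# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `medgxe`.

## Study design being modelled

The package targets a nested case-control design: a cohort observed over
several follow-up phases, with incident obesity cases (BMI ≥ 30 kg/m²)
individually matched 1:1 by sex and age (± 5 years) to controls who were
normal-weight (18.5 ≤ BMI < 25) at the phase the case became obese. The
scientific question is effect modification: does adherence to a
Mediterranean-style dietary pattern change the association between FTO
risk alleles (singly, or combined into a genetic risk score) and obesity
phenotypes (general obesity, abdominal obesity by waist circumference ≥
95 cm, and high waist-to-hip ratio)?

## Mediterranean diet score

Raw daily intakes are energy-density adjusted to grams per 1000 kcal
(`adjusted = raw × 1000 / energy_kcal`), which removes between-subject
energy scale: multiplying every intake and energy by a common factor leaves
all adjusted values, medians and scores unchanged (a tested invariant).
Cutoffs are sex-specific sample medians computed on the pooled analysis
sample (cases + controls); even-n medians are the midpoint of the two
central order statistics. Tie handling is asymmetric by construction:

* desirable components (vegetables, legumes, fruits+nuts, cereals, fish)
  score 1 **at or above** the median;
* undesirable components (meat & poultry, dairy) score 1 strictly **below**
  the median (an at-median intake scores 0);
* the MUFA:SFA ratio scores 1 strictly **above** the median.

Consequently a profile exactly at every median scores 5 (the five desirable
points), not 4: the asymmetry is intentional and follows the scoring rules
as stated, and the extremes 0 and 8 are attained exactly by all-below /
all-above profiles. A subject with SFA = 0 has an undefined ratio; it is
scored 1 (the limit of an infinite ratio exceeds any finite median) and
logged. Fruits and nuts are pooled into one component by default, giving
exactly 8 components; a configurable split (9 components) is provided.
Alcohol is not scored.

## Genotypes and the genetic risk score

Dosages count copies of the configured risk (BMI-increasing) allele.
The default six-SNP FTO panel (rs1121980, rs1421085, rs9939973, rs8050136,
rs17817449, rs3751812) carries equal odds-ratio weights of 8.18/6 ≈ 1.3633:
the analysis this package reproduces reports only the *sum* of its
literature weights (8.18), so the package does not invent per-SNP values;
users can supply their own weights through `SNPMeta`. Because of the n/Σw
normalisation the GRS range [0, 12] and the "one point per risk allele"
interpretation hold for any positive weights — an algebraic identity used
as a test oracle. Subjects with any missing dosage are excluded from GRS
analyses (complete-case, matching the complete-pairs design); no
imputation. The GRS is dichotomised at the sample median with high = GRS ≥
median.

Hardy–Weinberg equilibrium is tested by the plain Pearson chi-square on
genotype counts against n(p̂², 2p̂q̂, q̂²) with 1 df and no continuity
correction. A monomorphic SNP yields χ² = 0 with a warning. The statistic
is invariant to which allele is labelled minor.

VCF input accepts biallelic diploid records only; dosage is the count of
the configured risk allele among the two called alleles, and half-calls are
treated as missing.

## Exclusions, matching, quartiles

The exclusion cascade applies, in order: recent weight change > 5 kg,
pregnancy/lactation, weight-affecting medication, DNA quality failure, and
an energy-plausibility screen (reported/predicted intake outside mean ± 3
SD). The predicted intake defaults to a Schofield-type BMR equation (sex-
and age-banded linear functions of weight) times an activity factor (1.4 /
1.6 / 1.8 for low/moderate/high); a `predicted_energy_kcal` column
overrides it, keeping the screen testable without endorsing a particular
prediction equation. The audit log records removals per rule, and the
counts sum to input − retained.

Matching is randomized greedy: cases are visited in seeded-random order and
each draws a uniformly random eligible unused control (same sex, age within
the window, normal-weight at the case's phase). Unmatched cases are
dropped with a warning. The procedure is deterministic under a fixed seed.

MDS quartiles are rank-based with whole tie blocks kept together. Two tie
policies are provided. The default sends a block that straddles a cut to
the lower quartile (`ties="down"`); `ties="nearest"` sends it to the side
holding more of the block. On a discrete 0–8 score concentrated like
Binomial(8, ½) every quartile cut lands near a tie-block midpoint, so the
resulting blocks — and hence the per-quartile mean scores — are sensitive
to sampling noise under *any* deterministic rule; tests therefore validate
the assignment against a brute-force oracle of the rule itself rather than
against fixed per-quartile means. The 8-level analysis factor is the cross
of MDS quartile × a binary genotype flag (carrier under dominant coding, or
high GRS), with (Q1, flag = 0) as the reference; a `reference_high` option
flips the reference to Q4 for the alternative published convention.

## Conditional and unconditional logistic regression

For 1:1 pairs the conditional likelihood factorizes over pairs into
σ(dᵢ′β) with dᵢ the case-minus-control covariate difference — an
intercept-free logistic likelihood on the differences with outcome 1.
Concordant pairs (dᵢ = 0) contribute a constant and never move the
estimate or any likelihood-ratio statistic (tested). Both the conditional
and the unconditional (intercept included) fitters maximise the exact
log-likelihood by Newton–Raphson:

* convergence when max|score| < 1e-8 or max|step| < 1e-10, at most 50
  iterations;
* standard errors from the inverse observed information at the optimum;
* coefficients are capped at |β| ≤ 30 during iteration so separated fits
  stay finite; a covariate whose nonzero pair differences all share one
  sign is flagged as likely separation and the fit is returned
  non-converged with a diagnostic rather than raising;
* a singular information matrix raises; rank-deficient unconditional
  designs are rejected up front.

The sigmoid and log-sigmoid are evaluated in a tail-stable form. The
fitters are cross-checked in the test suite against closed forms (the
matched-pair OR equals the ratio of discordant counts; the 2×2 logistic
slope equals ln(ad/bc)), dense grid-search maximization, and statsmodels'
`ConditionalLogit` / `Logit` as independent implementations.

Interaction is tested by the likelihood ratio between nested fits with and
without the product term; the headline parameterisation is a single
carrier × ordinal-quartile (1–4) product, giving a 1-df χ² test, with a
categorical 3-df variant available. The trend test replaces the quartile
factor by the median score within each quartile and reports the Wald
p-value of that slope; per-genotype-stratum trends are read off a single
model containing trend, genotype and their product (carrier-stratum slope
= trend + interaction with the delta-method variance), which uses all
pairs rather than fitting within genotype-concordant subsets.

Adjustment sets follow the published tables: conditional obesity models
adjust for education only; abdominal-obesity and WHR models adjust for
education, age, sex, smoking, activity and energy and are fitted
unconditionally by default (a conditional option restricted to
outcome-discordant pairs exists). Wald 95% CIs use z = 1.96 with no
small-sample correction.

## Synthetic cohorts

The generator's defaults are the study conditions: n = 8000 subjects over
3 phases; minor-allele frequencies (0.38, 0.37, 0.38, 0.34, 0.33, 0.33);
energy log-normal with mean 2400 kcal/day and SD 1000; education ≥ 14 y
24%, current smoking 15%, low activity 41%; per-phase baseline obesity
incidence ≈ 3% so that a cohort of the default size yields roughly 600
matched pairs after exclusions and matching, the scale of the target
analysis.

Genotypes: each of two independent haplotypes draws a latent multivariate
normal vector with equicorrelation ρ (default 0.9, since the panel's SNPs
are tightly linked; ρ is a required, fully configurable field) and
thresholds it at the MAF quantile, so every SNP is in exact HWE marginally
while dosages are correlated across SNPs.

Diet: component intakes are log-normal around realistic daily medians,
scaled by the subject's energy so that energy-adjusted values are
energy-independent, as with real density adjustment. Because the score
compares continuous adjusted intakes with in-sample sex-specific medians,
each component point is Bernoulli(½) by construction and the MDS
distribution has mean 4 and SD ≈ √2 ≈ 1.41 — matching the target
population's reported mean 4.0, SD 1.44 structurally rather than by
tuning.

Outcomes: per-phase obesity probability is
logistic(β₀ + β_G·carrier + β_E·quartile + β_GxE·carrier·quartile +
covariate terms); once obese, a subject is a case at that phase. Optional
phase weights tilt accrual (the observed pattern 528/416/286 can be
supplied); the default is uniform. All randomness flows from a single seed
through spawned child streams, so stages are independently reproducible
and a fixed seed reproduces the cohort byte-for-byte.

For calibration studies, `simulate_matched_pairs` samples matched pairs
*exactly* from the conditional model: both members draw covariates, and
the case is the member A with probability σ(η_A − η_B) — precisely the
1:1 conditional likelihood — so conditional-logistic estimates are
consistent for the planted coefficients without simulating and matching a
full cohort. This is what makes 1000-replicate null calibration and
200-replicate × 5000-pair recovery runs take seconds.

What the generator does **not** emulate: item-level FFQ structure and
food-composition error, longitudinal weight trajectories (BMI is drawn at
the event phase, not evolved), dependence between diet and genotype,
informative loss to follow-up, and the real cohort's empirical MDS tie
pattern. Passing tests therefore demonstrate correctness of the
estimators and machinery under the assumed data-generating process, not
robustness to those real-data features.

## Problem sizes used in validation

Null calibration uses 1000 replicates of 500 pairs (rejection rate at
α = 0.05 compared with the binomial 99% interval); parameter recovery uses
200 replicates of 5000 pairs with β_GxE = −0.2 (mean bias and 95% Wald
coverage); HWE calibration uses 5000 simulated samples of 500 genotypes at
MAF 0.35; scoring equivalence uses 200 random profiles against an
independent straight-line re-scorer. These sizes give Monte-Carlo error
well inside the tolerances they are checked against.

## Known limitations

* The conditional fitter covers 1:1 matched sets only (the design it is
  built for), not general m:n strata.
* No exact conditional inference, Firth penalization or sandwich
  variances; separated fits are flagged, not rescued.
* Allele-frequency tables report counts derived from genotype counts; a
  published table whose allele and genotype counts disagree internally
  cannot (and should not) be reproduced cell-for-cell.
* Per-SNP GRS weights default to equal values preserving the published
  weight sum; analyses sensitive to weight heterogeneity must supply real
  literature weights.
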