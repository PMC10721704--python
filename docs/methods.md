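# Methods

`penescreen` implements a screen for phenotypic and genetic factors
associated with *absence* of cardiomyopathy symptoms in carriers of an
incompletely penetrant founder variant, driven end to end by a synthetic
cohort generator so every stage runs and is testable without restricted
biobank data. This note records the models, the generator's scope, and the
numerical and design choices.

## Four-group classification

Participants are partitioned by carrier status × symptom manifestation. A
participant is symptomatic when at least one configured self-reported
symptom (heart failure, heart attack, infarct, treated for arrhythmia) or
ECG sign (low voltages, negative T, ventricular tachycardia, ventricular
extrasystole, atrial fibrillation) is present at the baseline or follow-up
visit; for carriers a cardiac cause of death also counts. Missing flags are
treated as "not reported" — questionnaire non-response cannot assert
disease — and carriers with no ECG information at either visit are simply
classified on what remains rather than guessed; their count is visible in
the assignment table. Alternative symptomatic definitions (e.g. a patient
registry's outcome list) are expressed as a second `SymptomConfig` profile,
not separate code. The crude odds ratio uses a Wald interval on the log
scale with the Haldane–Anscombe 0.5 correction on zero cells.

## Kinship mixed model

The trait screen fits, per trait,

    y = Xβ + u + e,   u ~ N(0, 2Φ σ²_g),   e ~ N(0, I σ²_e)

with X = [1, age, age², sex, PC1–PC4, outcome] and Φ the pedigree kinship
matrix (φ_self = 0.5, parent–offspring 0.25). Pedigree kinship is computed
by the standard recursion and is block-diagonal by family, so 2Φ is
eigendecomposed block-wise once per analysis subset; the variance ratio
γ = σ²_g/σ²_e is then profiled by REML on a log grid ({0} ∪ 10^[−3,3], 32
points) with bounded Brent refinement (tolerance 1e-8) for single fits.
Coefficients are tested with Wald statistics on the normal scale, matching
the beta/SE reporting style of `lmekin`-type fitters. REML rather than ML
was chosen because the screen's contrasts have very unbalanced groups and
few carriers, where ML variance components are noticeably biased; the
reference implementation's choice is not documented, so this is recorded
as a package decision.

The batch fitter used for permutations evaluates many trait columns
against one design on the shared γ grid without scalar refinement: Wald
statistics are flat in γ near the optimum, and using the identical
procedure for observed and permuted columns keeps the permutation
comparison exchangeable. Correctness anchors: with 2Φ = I the fit equals
OLS to 1e-6; with fixed γ it equals an explicit-inverse GLS oracle to 1e-8;
on additive-genetic null traits its genomic control λ stays in [0.95,
1.05] while naive OLS inflates (λ > 1.05 and typically ≈ 1.3 at h² = 0.7).

A perfect linear fit (trait inside the design span) is handled by flooring
the residual sum of squares at 1e-300, which propagates to p ≈ 0 instead
of NaN. Non-PSD kinship raises with a jitter suggestion rather than being
silently repaired.

## Two-step screen and empirical q-values

Step 1 compares asymptomatic carriers (outcome = 1) with asymptomatic
non-carriers. Multiplicity over the correlated trait panel uses empirical
q-values from a pooled permutation null: per trait, B permutations shuffle
the trait values across participants while everything genetically linked
to the participant — kinship rows/columns, PCs, age, sex, carrier status —
stays attached; all permuted p-values are pooled and

    q(p_i) = [#{pooled p ≤ p_i} / B] / #{observed p ≤ p_i},

with a zero pooled count replaced by one (so min q = 1/B) and a running
maximum from the smallest observed p enforcing monotonicity. Pooling
across traits (rather than per-trait nulls) was chosen because the
procedure is defined on "the joint results for all variables"; the pooled
variant is also the one that makes q = 1/B attainable at rank 1. Age and
sex stay with the participant during permutation since they are
participant attributes, not trait attributes.

Step 2 refits the hits in two contrasts. "Confirmed" requires a same-sign
effect in asymptomatic-vs-symptomatic carriers AND an opposite-sign or
non-significant (two-sided p > 0.05, unadjusted) effect in
symptomatic-carriers-vs-asymptomatic-non-carriers — the pattern that
excludes a direct variant effect on the trait. Sensitivity re-runs use the
rank-based inverse-normal transform Φ⁻¹((r − 3/8)/(n + ¼)) (Blom offset,
average ranks on ties, missing preserved) and a 1:4 age/sex-matched
control subset, matched greedily without replacement, scarcest cases
first, nearest age first, ties broken by ID for determinism.

## Founder-haplotype window expansion

On the phased deletion-bearing chromosome copies of the carriers, the
window starts at the index variant and grows one variant per step,
alternating left/right (left first; on symmetric fixtures the order is
irrelevant, and asymmetric cases are covered by the brute-force oracle in
the tests). Adding a variant may split the modal haplotype group; when the
modal count would drop by strictly more than the split threshold, that
side freezes and the offending variant stays outside the window. Two
profiles: cohort MAF ≥ 0.01 with threshold 3, and carrier-chromosome MAC
≥ 4 with threshold 10. Spans are reported variant-to-variant in bp and,
when a gene interval is supplied, relative to it. Haplotype groups of at
least 3 carriers ("main splits") enter a 2×k chi-square test against
symptom status; when any expected cell is below 1 a label-permutation p is
substituted with a warning.

## Genome-wide scan and LD-confound screen

The scan runs on an unrelated subset: within each group, the younger
member of any pair with φ > 0.125 is removed (ties drop the
lexicographically later ID), then controls related to kept cases are
removed. Per variant, logit(outcome) ~ age + sex + PC1 + dosage is fitted
by batched Newton iterations (hundreds of variants per chunk, shared
covariate block); variants failing the group-specific MAF filters (cases
> 0.1, controls > 0.05) or INFO ≤ 0.4 are skipped with reason codes, and
quasi-separation (non-convergence or |β| > 15) flags the record with p set
missing — a plain-ML analogue of what a Firth fallback would rescue.

Genotype PCs are computed from the variance-standardized dosage matrix by
SVD, with an option to exclude whole chromosomes first: a founder
haplotype is a long-range-LD block, and when region variants are
over-represented (as in compact synthetic panels) the leading component
otherwise aligns with carrier status itself and degenerates the logistic
fits. The analysis drivers therefore exclude the founder chromosome from
PC computation, mirroring the standard practice of masking long-range LD
regions before PCA.

The LD-confound screen makes the usual by-eye line inspection
deterministic: among variants with p ≤ 5e-4, −log10(p) is regressed on r²
with the founder variant; externally studentized residual > 3 together
with r² < 0.1 flags "independent suggestive", everything else
"founder-LD". Both constants are arguments.

## Rare-variant burden tests

Per region (gene ± 50 kb, or hit ± 250 kb), qualifying variants (MAF ≤
tier ∈ {0.05, 0.01}, INFO > 0.8) are collapsed into a per-participant
minor-allele dosage sum and fitted with the same logistic model. Because
~40 cases against ~20,000 controls makes the asymptotic p anticonservative,
the reported p is calibrated by outcome-label permutations of a
covariate-adjusted score statistic (p = (1 + #{T_perm ≥ T_obs})/(1 +
n_perm)). This collapsing-burden + permutation design replaces a
robust-omnibus variance-component test: the inference reproduced is *which
regions associate*, not the omnibus statistic itself. Significant regions
(threshold 2.5e-6; compared on the permutation scale only when n_perm
resolves it, otherwise on the Wald scale) are split into ten equal-bp
segments (remainder to the last) and retested.

## Polygenic scores

Scores are Σ w_i × dosage of the effect allele, matched on (chrom, pos)
with orientation resolved by REF/ALT (swapped orientation uses 2 − DS);
strand-ambiguous A/T and C/G variants are dropped; excluded chromosomes
(e.g. the founder chromosome) are removed before matching, and zero
matches is an error, never a zero score. Group association uses
PGS ~ age + sex + outcome with the score coded as its continuous
percentile or as the >80th / <20th percentile indicator, and the same
pooled-permutation q-values as the trait screen. The interaction model is

    trait ~ age + sex + group + PGS + PGS:group

with the asymptomatic non-carrier group as reference and a Wald test per
PGS:group term; whether PGS:age and PGS:sex terms belong in the model is
an open design question
and PGS:sex terms, so both variants exist behind a flag with group-only as
default, and the fitted formula is recorded in the result metadata.
Per-group partial correlations (trait and PGS residualized on age + sex)
describe the interaction surface, and a rank-normalized refit is the
robustness check. Severity association is an ordinal Spearman trend of the
score against the count of signs among symptomatic carriers.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
utility. Defaults emulate the screened biobank: founder allele frequency
0.001 (carrier fraction 0.2%), background symptomatic prevalence 5.7%,
carrier log-OR ln 9 in a logistic penetrance model with age slope
0.05/year centred at 40 (giving >50% penetrance above age 60), pedigrees
mixing singletons with 2–3-generation families so carriers appear as
singletons plus 2–3-carrier families, a founder haplotype of ±690 kb
(~1.38 Mb) shared identical-by-descent with recombination truncating it in
~5% of carriers, and a default 12-trait ECG/anthropometric panel whose
only non-null carrier-related effects are the protective shifts HR +6.41
beats/min, QRS −5.7 ms and lnSDNN −0.216 in asymptomatic carriers. Trait
SDs are population-typical values (HR 11, QRS 10 ms, lnSDNN 0.40); the
penetrance intercept is calibrated numerically against the realized age
distribution because only marginal quantities are specified. A fixed seed
reproduces every output byte-for-byte.

What the generator does **not** emulate — hence what passing tests do not
show about real data: no genome-wide LD (background variants are unlinked;
LD exists only through the founder region), no imputation error model
(INFO defaults to 1; dosage noise is an option), non-carrier haplotypes
and background genotypes are not transmitted through the pedigree (family
structure enters traits and the founder region only), no ancestry
stratification unless constructed explicitly, and visit-2 values are a
noisy re-measurement (noise correlation 0.6), not a longitudinal model.
Two null-trait generators exist: a household model (whole family shares
one random effect — deliberately misspecified relative to 2Φ, used for
FDR calibration where permutation handles any covariance) and an
additive-genetic model drawing u ~ N(0, h²·2Φ) per family block, used for
genomic-control calibration where the mixed model's own covariance must be
the truth.

## Power calculators

Both calculators are two-sided Wald tests on the log odds ratio with
variance from expected cell counts (2×2 participant table for the carrier
design; allele-count table for the per-allele GWAS test, default α =
5e-8). They agree with Monte-Carlo simulation within ±3% when expected
cells exceed ~100, and are anchors rather than reproductions: the
quoted power figures they emulate do not pin down the test, sidedness, or group
fractions. Degenerate designs (expected cell < 1) warn and return NaN.

## Problem sizes

Experiments keep the asymptomatic-carrier group at its real size (~48),
which dominates the standard error of every carrier contrast
(SE ∝ √(1/48 + 1/N)), and thin the non-carrier pool to 1,500–3,000 — this
changes the contrast SE by under 1% relative to 34,201 controls while
keeping a full 50-replicate screen in minutes. Permutation counts use
B = 200 in the replicated experiments and B = 1000 in the single-run
analysis drivers; genomic-control experiments use 4,000 null traits
because median-based λ has sampling sd ≈ 3/√m. The burden calibration
keeps the full 40 vs 20,000 imbalance, since that imbalance is the thing
under test.

## Known limitations

Phasing, imputation, array QC and shrinkage-based PGS weight estimation
are upstream inputs, not implemented. The logistic scan has no Firth
fallback — separation is flagged, not rescued. The burden test is a
collapsing test only; it has no power against variance-component
(bidirectional) alternatives. Kinship from genotypes is a standardized-GRM
estimate, appropriate for threshold pruning but not a robust
relationship-inference method. The generator's crude OR is calibrated
through a conditional log-OR, so the realized marginal OR sits slightly
below the conditional target when penetrance varies with age; tests
compare against the analytically integrated expectation, not the
conditional value.
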