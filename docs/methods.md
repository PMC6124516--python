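# Methods

This note records the models `placentax` implements, the defaults and
why, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would want written down.

## Sex-biased expression

Counts are modelled per gene as negative binomial with a log link and a
per-sample offset. Size factors are classical median-of-ratios: sample
*j*'s factor is the median over genes of count/geometric-mean,
restricted to genes with a nonzero geometric mean; an all-zero matrix or
one without any such gene is a degenerate-input error.

The sex test is a two-group NB Wald test authored here rather than taken
from a DE framework. In a saturated two-group model the groups are
likelihood-orthogonal, so each sex's mean solves a one-dimensional score
equation Σⱼ (yⱼ − μ sⱼ)/(1 + α μ sⱼ) = 0, Newton-iterated on log μ and
vectorised across genes; the Wald SE of the log fold change is
√(1/I_F + 1/I_M) with I_g = Σⱼ μ sⱼ/(1 + α μ sⱼ) the expected
information. Dispersion α is method-of-moments on normalised counts
using the pooled **within-sex** variance (so a true sex effect does not
inflate it), clipped to [0, 10]. There is no dispersion shrinkage and no
fold-change shrinkage: per-gene p-values will therefore differ from
shrinkage-based engines, while the calling thresholds — which carry the
scientific content — are unchanged. Fold changes are reported from
normalised group means with a pseudocount of 0.5 for stability at low
counts. Conventions: an all-zero gene has fold change 1 and p = 1; a
gene with no variation has p = 1.

Calling thresholds (mean normalised count > 10, FC > 1.10 or < 1/1.10,
BH-adjusted P < 0.01 within the chromosome set) are the defaults
everywhere and live in `PipelineConfig`. The ">10% difference" rule is
interpreted symmetrically: the male-call threshold is the reciprocal of
the female one. BH runs over exactly the genes of the set under test
(chromosome X, or all autosomes jointly for the enrichment contrast);
ties need no extra rule under step-up. Enrichment is a two-sided Fisher
exact test on {X, autosome} × {biased, not}, Y excluded; an empty margin
returns p = 1 with a warning rather than an error.

## Promoter methylation

Windows are TSS ± 1,000 bp, 0-based half-open internally and clipped at
position 0; the window is symmetric so strand is irrelevant to the
interval. One TSS per gene is taken from the annotation row (multiple
annotated TSS per gene are not collapsed here; supplying a different
row is the configuration point). CpG calls on opposite strands of one
dinucleotide count as distinct positions unless the input pre-merges
them — the Bismark-coverage reader documents this.

The promoter statistic is Σ methylated / Σ total over the window's
distinct CpGs with ≥ 10× coverage, defined only when ≥ 4 CpGs qualify;
it equals the coverage-weighted mean of per-CpG methylation ratios (an
algebraic identity the tests assert on random fixtures). Duplicate
(gene, sample, position) records are an error — the statistic would be
ambiguous. Sex contrasts are per-gene differences of per-sex means over
defined levels; a gene missing one sex is reported missing, never zero.
Group tests run on per-gene female-minus-male differences (invariant to
gene-level methylation baselines): Mann–Whitney U of each category vs
the inactivated reference (scipy's exact path for tiny groups, tie-
corrected normal approximation otherwise) plus Kruskal–Wallis across
categories; an all-tied comparison returns p = 1.

## Escape classification

Classification is a pure function of the placental calls, the
cross-tissue partition and the annotation: female-biased and biased in
no comparison tissue → escaped placenta-specific; in ≥ 1 → escaped
common; male-biased → male-biased; expressed but unbiased →
inactivated; below the expression filter → unclassified. Lowly
expressed genes are deliberately excluded from the inactivated reference
(they carry no usable expression evidence), which is why "unclassified"
exists. Methylation is corroboration only: escaped genes are flagged
consistent when |ΔmCpG| < 0.1 (absolute promoter methylation
difference, configurable), inactivated and male-biased genes when
Δ > 0.1 with female hypermethylation; the flag never changes a
category, mirroring the use of methylation as group-level rather than
per-gene evidence. Prior-literature XCI labels are carried through for
reporting and never alter calls.

## Metabolite screen

Preprocessing: per (metabolite, run day), observed ion counts are
divided by the day's median — output medians are 1, making the step
idempotent; a cell with no observed value is an error naming the cell.
Missingness is assumed to mean "below detection", so missing values are
imputed with the metabolite's minimum observed relative abundance.

Stage 1 fits, per metabolite, a linear mixed model on natural-log
relative abundance over the early visits: subject random intercept;
fixed effects visit (categorical, 3 levels), sex, sex × visit. Visit is
categorical rather than linear in gestational age because the composite
hypothesis is "a sex difference at any of the first three visits"
(df = 3); a linear-GA variant remains available through the generator
config. Natural log is used because the base only rescales
coefficients, not p-values. The composite statistic is the joint Wald
χ² on all sex-containing coefficients from the REML fit; estimation
uses statsmodels `MixedLM` (the same single-random-intercept REML
objective a profiled one-dimensional optimiser would maximise) with a
Powell retry, because the bundled quasi-Newton path can diverge to a
singular covariance on null metabolites. Non-convergence flags the
metabolite and drops it from ranking. Ranking is by ascending p with
ties broken by metabolite id; exactly the top 10 proceed regardless of
p magnitude. Stage 2 is OLS of log 36 wkGA abundance on a sex
indicator in the same women; selection requires validation p strictly
below 0.01, so p = 0.01 exactly is not selected. The two-stage
structure keeps the validation data out of the screen, which is what
the false-selection calibration test relies on.

## Case-cohort risk analysis

Outcome algebra: PE = (f ∨ h ∨ i) ∧ term, FGR = (g ∨ j) ∧ term; a woman
can be both. Quintile cuts are the 20/40/60/80 empirical percentiles of
the noncase distribution; assignment is closed on the right (a value on
a cut falls in the lower quintile), cases use the noncase cuts, and
constant noncase values raise a degenerate-cuts error. The cohort-level
case proportion weights sampled noncases by the inverse subcohort
sampling fraction — a single cohort-level weight, because cases enter
the design exhaustively. Odds ratios come from unweighted
maximum-likelihood logistic fits (statsmodels GLM/IRLS, convergence
tol 1e-8), which are consistent for the OR under outcome-dependent
sampling; perfect separation raises an explicit error (detected via
saturated fitted probabilities / exploding coefficients), as does a
rank-deficient design, which names the collinear columns. The trend
test scores quintiles 1–5 as a continuous covariate — the conventional
reading of "linear trend" across quintiles. The continuous analysis
standardises log abundance to noncase mean 0 / SD 1 (log is the default
transformation; identity and square root are available) and reports the
OR per 1 SD with and without adjustment; categorical covariates enter
as indicator columns. Stratified analyses fit one continuous-Z model
per mutually exclusive case stratum against the shared control group;
strata with < 5 cases are fitted but flagged, and empty strata return a
missing OR without raising.

## The synthetic-data generator

The generator emulates the structure of a pregnancy cohort multiomics
study, and its defaults are the study conditions: 64 female / 67 male
placentas; a 4,177-woman cohort with a 325-woman random subcohort
(fraction 325/4177, weight 12.85); visits at 12/20/28/36 wkGA; an
837-metabolite panel with 2 sex-affected metabolites, run in batches of
36 with every visit of a woman in one batch and batches balanced in
case/control composition.

Expression: per-gene baseline means are log-uniform on [20, 2000]; NB
dispersion 0.05 (within-tissue expression variance is a free parameter
here, not an estimate from any dataset). Escaped X genes get female
mean = 1.5 × male mean by default; male-biased genes the reverse;
inactivated X genes and autosomes are sex-balanced (dosage
compensation); Y-like genes are male-only. About half the escapees are
"common" (female-biased in a random nonempty subset of comparison
tissues), the rest placenta-specific.

Methylation: beta-binomial per CpG (overdispersion 0.05 — biological
variability beyond binomial sampling) with category means 0.55/0.15 for
inactivated promoters in females/males, 0.15 in both sexes for escaped,
0.55/0.15 for male-biased; Poisson coverage around 30×; ≥ 4 CpGs per
promoter; 2 samples per sex by default.

Metabolome: log-scale model with subject intercept SD √0.5 and
residual SD √0.5 (total variance 1, so effects are in SD units).
`sex_effect_size` (default 0.5) is the planted female-minus-male
difference at the first visit; a sex × gestation interaction grows it
by up to +50% at the last visit, emulating feto-placental synthesis.
Run-day batch factors are log-normal with SD 0.2; values below the
per-metabolite 5% quantile are left-censored to missing (missing =
below detection, matching the imputation assumption). Outcomes are
generated at full-cohort level from a logistic model on the target
metabolite's standardised last-visit level, then case-cohort sampling
is applied, so the sampling weight is recoverable from the generated
design. The slope magnitude 0.61 (PE positive, FGR negative) is
calibrated numerically so the model-implied case-proportion ratio
between extreme noncase quintiles of the *measured* metabolite is
5-fold, accounting for within-quintile averaging and ≈ 0.975
measurement reliability; intercepts −3.58 / −3.38 give marginal
prevalences of ≈ 134 and ≈ 162 cases per 4,177. Case-group flags are
assigned within outcomes (PE split f/h/i ≈ 0.52/0.17/0.31 so severe ≈
92 and nonsevere ≈ 42 per 134; FGR phenotype strata ≈ 0.32/0.49/0.19
matching 52/79/31 per 162); a small fraction of remaining women get
non-analysed case groups a–e, with a/b/e marked preterm.

What the generator does **not** emulate: read-level sequencing noise,
GC/mappability artefacts, real genome coordinates (toy chromosomes
chr1…chr22/X/Y with evenly spaced TSS), correlated metabolites,
assay drift within a run day, informative missingness beyond left
censoring, or confounding between covariates and exposure (adjusted and
unadjusted ORs therefore agree in expectation on synthetic data).
Passing tests demonstrate correctness and calibration of the
*machinery* under the planted model, not performance on real cohort
data.

## Problem sizes

The full-scale defaults are practical for single runs (an 837-metabolite
screen is ~2 minutes), but the test suite and the acceptance script use
reduced panels chosen to keep the whole suite under two minutes while
preserving the conditions each check needs: expression recovery and
calibration at 60/sex and 30/sex with 100–150 X genes; the screen on
panels of 12–200 metabolites at cohort sizes 1,200–4,177; the risk
gradients pooled over 25 cohort-scale replicates with a 2-metabolite
panel (only the target matters there); 200 replicates for the null
false-call rate and the CI-coverage checks.

## Numerical conventions

Wald p-values are two-sided normal/χ² tail probabilities. Logistic CI
bounds use ±1.96 × SE on the log-odds scale. Newton steps in the NB
mean solve are clipped to ±5 on the log scale with a floor of half a
normalised count. All generator randomness flows from a single seed
through named `SeedSequence` streams, so adding a generator never
perturbs another's draws; equal seeds give byte-identical written
reports (fixed column orders, `%.10g` floats, sorted JSON keys).
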