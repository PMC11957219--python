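# Methods

`cnvsleep` implements a genome-wide copy-number-variant (CNV) burden analysis
of sleep duration and cognitive ability, together with a synthetic cohort
generator that reproduces the statistical structure those analyses assume.
This note records the models, the defaults and their units, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Burden statistic

Each gene carries a LOEUF score (loss-of-function observed/expected
upper-bound fraction) on [0.03, 2]; lower values mark genes intolerant to
haploinsufficiency. For individual *i* and CNV type *t* ∈ {DEL, DUP},

    burden_i,t = Σ_{g ∈ G_i,t} 1 / LOEUF_g

where *G_i,t* is the set of distinct genes overlapped by the individual's
type-*t* calls. Genes are counted once per individual and type however many
calls cover them; genes without a LOEUF annotation contribute nothing.
Per-gene contributions are therefore bounded in [0.5, 33.3]. Genes are also
counted in four intolerance categories — [0.03, 0.2), [0.2, 0.35),
[0.35, 1), [1, 2] — with every lower bound inclusive and the tolerant bin
closed at the top.

Overlap is any shared base pair between half-open intervals (internal
coordinates are 0-based half-open; the GTF reader converts on ingestion).
No overlap-fraction threshold is applied to gene bodies: a 1-bp rule is the
simplest defensible choice and lives behind a single predicate
(`annotate_cnvs(..., overlap="containment")` switches to full containment).

## Recurrent-locus carrier calling

An individual carries a recurrent locus when a same-type call overlaps the
locus critical interval by at least 40% of *both* lengths (reciprocal
overlap), a conventional CNV-matching criterion; the threshold is a single
parameter. Loci enter the association scan only with strictly more than 10
carriers among the analyzed rows. Scans fit one regression per locus ×
phenotype — least squares for continuous phenotypes, logistic for probable
insomnia — with age, sex and 10 principal components as covariates, and
correct for multiple testing by Benjamini–Hochberg FDR within each
phenotype, separately for deletion and duplication loci. Non-carriers are
the reference group. Non-converged logistic fits are flagged and excluded
from their FDR family.

## U-shape protocol

For an exposure *x* (sleep duration in hours, or the burden analyses with
exposure and outcome swapped) the protocol is:

1. exploratory covariate-adjusted smooth of the outcome on *x* — an
   unpenalized cubic B-spline basis (default 10 functions) fit by least
   squares; no inference is attached to the smooth;
2. linear and quadratic least-squares fits on the same rows (listwise
   deletion over all variables);
3. likelihood-ratio comparison, 2·(ℓ_quad − ℓ_lin) against χ²(1); the
   quadratic model is preferred below α = 0.05 (two-sided, the package's
   reading of "significant ANOVA");
4. vertex = −B/(2A), the exposure value at the parabola's extremum, where A
   is the squared-term and B the linear-term coefficient on the original
   exposure scale.

The exposure is mean-centered before squaring for conditioning; A and B are
back-transformed so the vertex formula applies on the natural scale. The
vertex is reported only when |A| > 1e−10. Collinear covariates are dropped
greedily (never the exposure terms) with a warning; zero exposure variance
is an error. Sleep–cognition fits adjust for age at sleep report and the 10
PCs; burden regressions adjust for age, sex and the 10 PCs.

## Stratified gene-count regressions

Per LOEUF category *j*, CNV type and phenotype:

    Y_i ~ β0 + β1·(# genes of individual i inside category j)
             + β2·(# genes outside category j) + β3·age + β4·sex + 10 PCs

β1 is the per-gene effect of category-*j* genes adjusted for the rest of the
individual's same-type gene content. Inside and outside counts partition
the individual's LOEUF-annotated covered genes. A category with zero count
variance is skipped with a warning.

## Mediation

Burden → sleep-deviation → cognition is decomposed by the
product-of-coefficients method for the linear–linear case: mediator model
M ~ X + C and outcome model Y ~ X + M + C, ACME = a·b, ADE = the outcome
model's X coefficient, total = ACME + ADE (an exact OLS identity), and
proportion mediated = ACME/total (undefined when |total| ≤ 1e−10).
The default mediator is |self-reported sleep − cohort mean| in hours, which
linearizes the U-shape so a linear mediation model is coherent; plain
duration is available by flag. Uncertainty is a nonparametric bootstrap:
individuals resampled with replacement (default 1000 draws, seeded),
percentile 2.5/97.5 intervals, and two-sided p-values equal to twice the
fraction of draws crossing zero, floored at 1/n_boot. Point estimates are
always the full-sample values.

Because self-report is rounded to whole hours and carries reporting noise,
the observed-mediator regression paths are mildly attenuated relative to the
latent deviation paths; the population estimand of the procedure (measured
on a very large simulated cohort) is therefore the correct coverage target
for the bootstrap intervals, while recovery of the latent proportion
mediated is checked with a wider Monte-Carlo tolerance.

## Synthetic cohorts

The generator emulates all five analysis inputs on one synthetic
chromosome: non-overlapping genes with uniform LOEUF on [0.03, 2] (no
empirical LOEUF marginal is targeted; uniformity balances category
occupancy), Poisson-count CNV calls with lognormal lengths, a
recurrent-locus table with Bernoulli carrier implants, and a phenotype
table. The phenotype model:

* deviation d_i = θ·(burden_DEL + burden_DUP) + |N(0, τ)|, τ = 1.0 h
  (half-normal noise keeps the magnitude non-negative);
* sleep_i = 7.15 + s_i·d_i + N(0, 0.1), s_i a fair ±1 coin — burden scales
  the *magnitude* of the deviation, so the linear burden–sleep effect is
  zero and the association is purely U-shaped;
* self-report = sleep rounded to the nearest hour; an accelerometer subset
  (fraction 0.19) keeps the continuous value and gains a Beta-distributed
  efficiency (mean 0.76, SD 0.07) and a wear-days count;
* cognition_raw = −β_DEL·burden_DEL − β_DUP·burden_DUP − λ·d + N(0, 1),
  re-standardized; executive-function tasks are attenuated, noisier copies;
* probable insomnia ~ Bernoulli(0.28), independent of burden (the null
  effect is the default; a log-odds effect is configurable);
* 1% of sleep records are replaced by out-of-range values so the QC filters
  are exercised in every run.

Defaults encode the study conditions: β_DEL = 0.04 and β_DUP = 0.0919 z per
unit Σ1/LOEUF; mean sleep 7.15 h with total self-report SD ≈ 1.09 h
(τ = 1.0 and reporting noise 0.1 h on top of hour-rounding); θ = 0.02 h per
unit burden and λ = 0.0943 z per hour, chosen so the implied proportion
mediated for deletions, θλ/(β_DEL + θλ), is 4.5%. CNV rate 0.3 events per
individual per type with median length 50 kb (lognormal σ = 0.8) keeps the
variance in burden at a level where burden explains ≪ 5% of cognition
variance, as in population cohorts. One global seed derives independent
per-stage substreams, so any stage re-run from cached inputs is
bit-reproducible.

What the cohorts do *not* emulate: SNP-array intensities or CNV-calling
error (calls are truth), linkage/ancestry structure in the PCs (independent
noise), age/sex effects on cognition, realistic Σ1/LOEUF marginals, and raw
accelerometer signal (efficiency is emitted directly; the
sleep-period-time definition is documented for users supplying derived
values). Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed generating model, not robustness to calling
error or confounding.

## Phenotype QC

Exclusion bounds follow strict inequalities: self-reported or accelerometer
durations below 3 h or above 12 h are set missing (records retained for
other phenotypes, so per-analysis sample sizes differ by phenotype);
accelerometer measures are removed below 5 wear-days; the sensitivity
subset removes individuals strictly above 65 years and/or on interfering
medication. Probable insomnia codes "sometimes"/"usually" as cases,
"never/rarely" as controls, and refusals as missing. Cognitive scores are
z-scored by residualizing on age and sex and scaling residuals to unit SD
(residualization rather than stratified norms — the simplest construction
satisfying the stated properties); a constant sex column falls back to
age-only adjustment with a warning. All filters are idempotent and never
touch identifiers or covariates.

## Problem sizes and test design

Acceptance-level checks run at n = 20,000 individuals (50 replicates for
U-shape power/vertex and for the null size check), 200 replicates of
n = 5,000 for mediation CI coverage (400 bootstrap draws per replicate;
the single recovery run uses 1000), 100 replicates of n = 4,000 for the
null FDR scan, and 50 random 200-individual instances against the
exhaustive all-pairs burden oracle. The coverage target is the population
ACME measured once on an n = 300,000 cohort. These sizes keep Monte-Carlo
error small relative to each tolerance while the full suite runs in
minutes.

## Known limitations

* The mediation model assumes sequential ignorability; no sensitivity
  analysis is provided, and with pleiotropy (burden affecting sleep and
  cognition through separate paths — the generating model's default) the
  small mediated fraction is an associational decomposition, not proof of a
  causal pathway.
* The U-shape LRT's χ²(1) reference is asymptotic; at a few hundred rows it
  is mildly anticonservative.
* Gene–CNV overlap ignores strand and exonic structure; whole gene bodies
  are matched.
* The logistic scan requires enough carrier cases; quasi-separation is
  flagged rather than penalized (no Firth correction).
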