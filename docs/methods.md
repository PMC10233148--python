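# Methods

`nirblup` implements the statistical chain used when a breeding program
predicts expensive end-product (EP) quality traits with the help of a
cheap, correlated NIR-predicted proxy: phenotype adjustment, genomic
relationships, single- and bivariate GREML/GBLUP, masking-scheme
cross-validation, and forward prediction across breeding cycles. This
note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Phenotype adjustment

Raw trial records are first edited for outliers per trait: a single pass
removes records outside mean ± 4 SD, with both moments computed once on
all records of the trait (sample SD, ddof = 1). There is no iteration,
so a gross outlier that inflates the SD can survive — that is inherent
to a non-iterative edit and is covered by a test.

Adjusted phenotypes are BLUEs from the fixed-effects model

    value = mean + trial + line + error,

where *trial* is the concatenated `year_location_nursery` group label.
The model is solved by OLS with corner-point constraints (first trial
and first line as reference); the reported BLUE is `intercept + line
effect`, so BLUE *differences* are free of trial effects while the
absolute level carries the reference trial's effect (harmless: every
downstream use is correlation- or difference-based). The line-by-trial
incidence graph must be connected, otherwise BLUEs are not comparable
across components and the fit raises an error naming the components.
Lines aliased with a trial are reported with infinite standard error via
an estimability check (`c` must lie in the row space of the design).

Broad-sense heritability on a line-mean basis is

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / (T R)),

with `sigma_g^2` the line variance from a REML fit of the same model
with *line* random (a single variance ratio, maximized by bounded scalar
search on log lambda with a profiled residual variance), and T, R the
mean numbers of distinct trials per line and replicates per line-trial.

## Genomic relationship matrix

`G = W W' / (2 sum_j p_j (1 - p_j))` with `W` the dosage matrix centered
at twice the observed allele frequency (VanRaden's first method).
Frequencies come from the observed sample; missing dosages are
mean-imputed, i.e. contribute zero after centering. A minor-allele
frequency filter is available but defaults to off. Because REML needs an
invertible phenotypic covariance, `grm_condition` adds a diagonal ridge
(default 1e-6) only when the smallest eigenvalue falls below 1e-8, and
records the amount added. PCA of G is a plain eigen-decomposition with
scores scaled by the square root of the eigenvalues.

## GREML and GBLUP

Single-trait model: `y = 1 mu + Z u + e`, `u ~ N(0, G sigma_g^2)`,
`e ~ N(0, I sigma_e^2)`; narrow-sense heritability is reported as
`sigma_g^2 / (sigma_g^2 + sigma_e^2)` on the adjusted-phenotype scale.
The bivariate EP/NIR model stacks the two trait vectors with per-trait
intercepts, genetic covariance `G0 (x) G` (2×2 between-trait covariance
Kronecker the GRM) and unstructured 2×2 residual covariance `R0`, whose
off-diagonal element binds only lines observed for both traits. Records
missing for a trait are absent rows of the likelihood, never imputed.

The restricted log-likelihood is

    l = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],

with the additive constant `-(n-p)/2 log 2 pi` dropped everywhere.
Maximization uses average-information (AI) REML: all six (or two)
parameters enter V linearly, so scores and the AI matrix come from
structured multiplications with the GRM blocks. Numerical safeguards,
in the order they act:

- starting values: half the per-trait phenotypic variance for the
  variances, zero for the covariances;
- after every proposed update, `G0` and `R0` are projected back into the
  PSD cone by eigenvalue clipping (floor 1e-8 times the mean phenotypic
  variance), and variances are floored at the same scale;
- step halving (up to 14 halvings) on any AI step that does not improve
  the likelihood, then a scaled gradient step as fallback;
- variances pinned at the floor with a negative score are dropped from
  the AI system for that iteration (otherwise they stall the rest);
- convergence when the likelihood change is below `tol` (default 1e-6)
  and the maximum relative parameter change below 1e-6, or when the
  likelihood has gained less than `5 * tol` over the last five accepted
  iterations (accepted steps are monotone, so this is a diminishing-
  returns stop that also covers zigzagging along the PSD boundary when
  the genetic correlation estimate hits |r_g| = 1), or when no ascent
  direction remains at line-search resolution;
- exceeding `max_iter` (default 100) raises a convergence error carrying
  the iteration trace; cross-validation records such folds as failed and
  excludes them from summaries.

Standard errors come from the inverse AI (observed-information) matrix
at the optimum; the SE of `r_g` uses the delta method. They are
curvature-based approximations, labeled as such.

GEBVs for *every* line in the GRM — phenotyped or not — are the BLUP
conditional means `Cov(u, y) V^-1 (y - X b_hat)`. Tests pin this to two
independent routes: a dense conditional-mean assembly on a toy instance,
and the GBLUP/SNP-BLUP duality (GEBVs equal `W a_hat` from marker ridge
regression with shrinkage `c sigma_e^2 / sigma_g^2`, exact only on the
unconditioned GRM).

The phenotypic correlation between the trait pair is by default the
Pearson correlation of the two BLUE vectors over doubly-observed lines;
a variance-component-based alternative `(G0 + R0)` correlation is
available as an option, since either definition is defensible.

## Validation schemes

Folds are drawn over lines, never records. Scenarios differ only in the
NIR records accompanying the EP training data: S0 none (single-trait),
S1 only non-validation lines carrying both traits, S2 additionally the
whole NIR-only pool, S3 additionally the validation candidates' own NIR
records. Training information is therefore nested S0 ⊆ S1 ⊆ S2 ⊆ S3,
and the held-out EP values never enter any training structure — this is
asserted on every fold and raises on violation. Accuracy is the raw
Pearson correlation between held-out BLUEs and GEBVs, with no
heritability rescaling.

Forward prediction assigns each line to its first observation year;
training for test year k uses every line first observed before k (EP
always, NIR too in `multi` mode), so lines seen in both periods are
training members. Per-year accuracies and their mean are reported.

## The synthetic generator

The generator emulates the *structure* of a commercial wheat quality
program: yearly cohorts of lines, a trial layout per year, an expensive
EP assay on few lines and an NIR proxy on many, severe year-to-year
imbalance, and a pair of genetically correlated traits per line.

- Genotypes: per-marker alternate-allele frequency uniform on
  `maf_range`, binomial(2, p) dosages; optional half-sib family blocks
  share one parental gamete per family. Frequencies above 0.5 are
  allowed (major-allele coding) so degenerate fixed-marker setups are
  expressible.
- Breeding values: `u = W a` with a 2×m marker-effect matrix drawn
  bivariate normal and then linearly rescaled so the *realized* 2×2
  genetic covariance equals the target exactly (phenotypic variance is
  normalized to 1 per trait, so the genetic variances equal the target
  heritabilities). Exact realized truth is what makes tight recovery
  tests possible at any n.
- Records: each cohort line is observed in its year in `reps_per_line`
  of the year's trials; trial effects are i.i.d. normal per (year,
  trial) and shared by all records of a trial; residual EP/NIR pairs are
  drawn per (line, trial) with correlation `r_e`. A small set of check
  lines is grown in every trial of every year, which keeps the trial
  design connected across years — exactly the role checks play in real
  programs.
- Missingness: per-year, per-trait line counts are imposed exactly, with
  nested selection (the smaller trait's lines are a subset of the larger
  trait's where possible) so the double-phenotyped overlap needed by the
  paired scenario exists by construction. Checks are retained
  preferentially because they carry the connectivity.

Default headline parameters (h2_ep = 0.6, h2_nir = 0.7, r_g = 0.8,
r_e = 0.3, trial-effect SD = 1.0) sit in the middle of the ranges
reported for wheat end-product quality traits and their NIR proxies
(heritabilities roughly 0.3–0.7, genetic correlations 0.2–0.86). The
residual correlation is not separately reported for such programs; 0.3
is a plausible mild value and only matters for the paired scenario.

What the generator does **not** emulate: linkage disequilibrium or
genetic maps (markers are exchangeable columns), selection or
multi-generation pedigrees, genotype-by-environment interaction, spatial
field trends, and NIR spectra themselves (the NIR trait is a correlated
phenotype, with instrument error folded into its residual). Passing
tests therefore demonstrate correctness of the estimators and schemes
under a well-specified additive model — not robustness to LD structure,
GxE, or calibration drift in real data.

## Problem sizes used by the test suite

Tests scale the study down to run on one CPU in minutes, keeping the
design features that matter:

- parameter recovery: 400 lines × 1,000 markers, both traits on every
  line, one record per line-year, 10 fixed seeds; mean estimates are
  checked within ±0.10 (h²) and ±0.15 (r_g). The h² means land ~0.05
  below the generating values because BLUE adjustment leaves a little
  trial-estimation noise in the working phenotype; the GREML stage
  itself is unbiased (verified separately against truth-plus-noise
  phenotypes).
- scenario comparison: 250 EP lines with a 5× pool of NIR-only lines
  (1,492 NIR lines total), 800 markers, fivefold × 3 repeats; S2 and S3
  beat S0 by ~+0.26 and ~+0.37 mean accuracy, S1 is statistically
  indistinguishable from S0 at this size.
- forward trend: 8 years with cohorts growing 30→150 lines (the growth
  pattern real programs show), 400 markers, 10 seeds; the upward trend
  is asserted on per-seed regression slopes.

## Known limitations

- Dense O(n³) likelihood evaluations cap comfortable problem sizes at a
  few thousand records per fit; the real-scale datasets these methods
  are used on (tens of thousands of NIR records) need sparse or
  factored solvers that are out of scope here.
- Only two traits; no multi-environment covariance structures.
- BLUE standard errors are not propagated into GREML as weights; the
  residual of the working phenotype is assumed homoscedastic per trait.
- The one-pass outlier edit uses global per-trait moments; per-trial
  editing would behave differently on strongly shifted trials.
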