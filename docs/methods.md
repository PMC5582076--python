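# Methods

This note documents the statistical models implemented in `dhgs`, the
synthetic-data generator that supplies the study conditions, the numerical
choices, and what the test suite does and does not establish about real
data.

## The prediction models

Both predictors are single-random-effect linear mixed models
`y = Xβ + g + ε` over `n` lines, differing only in the covariance of the
genomic effect.

**GBLUP.** `g ~ N(0, G σ²_A)` with the VanRaden realized relationship
matrix `G = ZZ′ / (2 Σ p_i (1 − p_i))`, where `Z = a − 2(p_i − 0.5)` on
genotype codes `a ∈ {−1, 0, +1}` and `p_i` is the second-allele frequency
at locus `i`. Allele frequencies are computed from *all* lines in the
supplied matrix (training plus selection candidates): candidate genotypes
are available at prediction time, so no phenotype information leaks.
Monomorphic markers contribute nothing to numerator or denominator and are
dropped. Variance components are estimated by exact REML: with one random
effect, the restricted likelihood is a one-dimensional function of the
variance ratio `δ = σ²_ε/σ²_A` once `G` is spectrally decomposed, so the
optimum is found by a log-grid scan (10⁻⁸…10⁸) plus bounded scalar
refinement to 10⁻⁸ on log δ — no iterative mixed-model solver, no
convergence ambiguity. GEBVs for any line in `G` (phenotyped or not) are
`G[·, train] (G[train, train] + δI)⁻¹ (y − Xβ̂)`; for training lines this
equals the mixed-model-equation solution, and with matched shrinkage it is
algebraically identical to ridge-regression BLUP of marker effects (a test
verifies the identity to machine precision).

A point worth flagging: for fully inbred DH material the diagonal of the
VanRaden `G` is close to 2 (inbreeding coefficient 1), so the genetic
variance realized among the lines is about `2 σ²_A`, not `σ²_A`. The
`heritability` property therefore scales `σ²_A` by
`mean diag(R) − mean(R)` — the variance of line effects implied by
`g ~ N(0, R σ²_A)` — before forming the ratio. Without this correction a
population simulated at h² = 0.5 would appear to have ĥ² ≈ 0.33 purely by
definition.

**RKHS regression.** `u ~ N(0, K σ²_u)` with the Gaussian kernel
`K(x_j, x_k) = exp(−h · mean_l (x_jl − x_kl)²)`; the bandwidth `h` sets how
fast similarity decays with marker distance (DH lines opposite at every
marker have mean squared difference 4, so `K = e^(−4h)`). The model is
fitted by a Gibbs sampler in the eigenbasis of `K` (components below
10⁻¹⁰ of the largest eigenvalue dropped): normal updates for β and the
kernel effects, scaled-inverse-χ² updates for `σ²_u` and `σ²_ε` with 5
prior degrees of freedom and prior scales splitting the sample variance of
`y` equally. Chain defaults are 12,000 iterations, 2,000 burn-in, thinning
5, fully seeded; a variant with frozen variance components (degenerate
priors) exists for validation against the closed-form BLUP, with
batch-means Monte-Carlo standard errors (25 batches) that honestly account
for chain autocorrelation. Unphenotyped lines are extended through the
kernel rows at the posterior-mean variances. A diagonal jitter of 10⁻⁸ is
permitted before factorization; larger rank deficiency is an error.

**Covariates.** Heading date and rust variables enter either as fixed
effects — the validation-line score is then `x′β̂ + GEBV`, since these
covariates are observable on selection candidates — or as phenotype
correctors: ordinary least squares of the response on the covariate, fitted
on the training folds only, with validation lines scored against their
corrected phenotype. Both routes are first-class; they are genuinely
different models and give different abilities.

## Validation engine

Predictive ability is the Pearson correlation `r(GEBV, Obs)` over
validation material. Within-year: k-fold cross-validation (default k = 10)
repeated (default 5×) with different random foldings; per replicate the
holdout predictions of all lines are assembled and correlated once. The
reported value is the replicate mean, with SE = SD over replicates / √reps
(the natural definition for a handful of replicates; fold-level
correlations would mix two variance scales). Fold sizes differ by at most
one; folds with fewer than 3 validation lines are an error. Cross-year
prediction routes the training year through the same holdout scheme and
correlates each replicate's assembled predictions with the *other* year's
observed phenotypes, so the two estimates share a footing; a no-holdout
whole-population fit is available as an option. Rust covariates are
screened one at a time (each as a single fixed covariate, scored by
within-year CV); the bandwidth grid default
{0.01, 0.05, 0.1, 0.25, 0.5, 1, 2, 5} spans the region 0.1–1 where the
Gaussian kernel typically peaks, with ties broken toward smaller h.

## G×E-corrected BLUP training

The plot-level two-way model `y = year + line + year×line + ε` (independent
random line and interaction effects) is estimated by REML through
statsmodels' mixed linear model — the established tool for this ordinary
model fit — with optimizer fallbacks, and the BLUPs are then recomputed
exactly from the generalized-least-squares equations at the estimated
variances (verified against the balanced-design closed form
`l̂ = shrinkage × (line mean − grand mean)` to 10⁻⁶). Lines without
within-year replication confound interaction with plot residual and are
excluded; purely mean-level data are accepted with a warning, with the
interaction variance reported as zero (inestimable). The line BLUPs — shrunk
two-year means — then serve as the training response for both predictors,
with no environmental covariates; ability is scored against each single
year's observed means. Negative variance estimates are clamped at zero.

## Marker thinning

Greedy keep-first scan in stored marker order: a marker is retained iff its
absolute Pearson correlation with every already-retained marker is below
the threshold `t`; removal is at `|r| ≥ t` (with a 10⁻⁹ tolerance so that
numerically computed perfect correlations are removed at `t = 1.0` — exact
duplicates must not survive the loosest threshold). Zero-variance markers
are dropped with a warning. In the experiment the correlation matrix is
computed once per fold from the **training lines only** and reused across
the threshold grid; the relationship matrix is rebuilt on the retained
markers before fitting. Thresholds leaving fewer than 10 markers are
flagged, not failed. Note that greedy keep-first does not *guarantee*
monotone retained counts in `t` (removing an early blocker can readmit
later markers); on LD-structured genotype data the profile is monotone in
practice, and the tests check it there.

## Ranking consistency

Per year and model, lines are ranked by GEBV ascending (lowest = 1, ties
get average ranks); a line's year index is the mean of its ranks over the
model set — four models for the non-G×E set (best within-year and best
cross-year, each for GBLUP and RKHS, "best" chosen from the scenario table
with ties broken by lower SE), two for the G×E set. Sorting by the year-1
index from highest to lowest (ties by line id), the ranking distance is
`d = |index₁ − index₂|` and the profile is the running mean
`d̄_n = Σ₁ⁿ d / n`. `d̄_N` over the whole population is invariant to the
sort order; the intermediate values are not, by design — they isolate the
top of the ranking. When the same model composition happens to be selected
as best for both target years, its two rankings coincide and the profile
contribution is zero; this is a property of the selection procedure, not a
bug.

## Synthetic data: what it emulates

One biparental cross of a selfing cereal: parents fixed for alternate
alleles, each DH line a doubled F1 gamete, so genotypes are ±1 everywhere
and every marker segregates at expected frequency ½. Crossovers follow the
Haldane (no-interference) model — recombination fraction
`r = ½(1 − e^(−2d/100))` for loci `d` cM apart — chosen for its closed
form, which makes the recombination machinery directly testable. Default
genome: 21 chromosomes × 150 cM, 270 evenly spaced markers each (explicit
marker positions can be supplied); the source material reports no map, so
these are modeling choices.

Trait architecture: 300 QTL (yield treated as polygenic; with far fewer
QTL the realized year-to-year interaction structure is unstable across
seeds) with standard-normal additive effects, optional epistasis as random
QTL-pair products carrying a set fraction of genetic variance, and
empirical rescaling so that `h² = var_add / (var_g + resid_sd²/n_reps)` —
heritability on a line-mean basis, **excluding** the line×year interaction
from the denominator so that h² and the between-year correlation are
separately tunable. With `resid_sd = 0` the scaling is skipped (any genetic
variance satisfies the target).

Trials: plot yield = year mean + genetic value + line×year interaction +
plot residual, two replicates per line-year. Year means default to 1579.73
and 2228.03 kg/ha with plot residual SD 250 kg/ha. The interaction is
**marker-associated by default** (`gxe_mode="genetic"`): the causal loci
receive fresh effects each year, rescaled so the interaction SD among lines
is exactly `gxe_sd`. This matters: if the interaction were iid line×year
noise, a holdout line's interaction would be equally unpredictable within
and across years and within-year CV would *not* be optimistic — the
inflation phenomenon requires the year-specific signal to be learnable from
markers, which is also the standard quantitative-genetics reading of
G×E in a biparental population (QTL-by-environment). `gxe_sd` defaults to
the closed-form value that sets the between-year correlation of line means
to 0.417 given h², `resid_sd`, and `n_reps`
(`ρ = var_g / (var_g + gxe_sd² + resid_sd²/n_reps)`).

Covariates: heading date = year offset (170.37 / 161.81 days) + a
component with configurable correlation (default 0.3) to genetic value +
noise (SD 2 days). Rust severity (integer 0–9) and incidence (percent
0–100) are scored in year 2 only at two time points, the second shifted
upward, with configurable correlation (default 0.5) between the latent
severity and the non-genetic deviation of the year-2 line means — so rust
is informative about the residual, which is why including it as a covariate
can raise predictive ability.

Missingness: per-marker call rates drawn from a Beta distribution (default
mean 0.6, SD 0.15 — GBS coverage is heavy-tailed), entries dropped
independently within a marker. All stages draw from independent substreams
of one integer seed (CRC-tagged SeedSequence), so every pipeline output is
bit-reproducible.

**What the generator does not emulate:** read-level GBS error, calling
artifacts, non-random (coverage- or allele-dependent) missingness,
population structure beyond a single cross, spatial field trends,
year-specific error variances, or selection during line development.
Passing tests therefore establish internal correctness and the *direction*
of the studied effects under clean assumptions, not effect sizes on any
real dataset.

## Imputation

*Mean imputation* replaces each missing entry by its marker's observed mean
(real-valued; imputed genotypes are never re-rounded to codes, since both G
and K operate on numeric values and rounding discards information).

*EM imputation* models each marker column as an n-variate normal with the
marker's own mean and a shared line-by-line covariance — the
relationship-based formulation that suits GBS shapes, where markers vastly
outnumber lines and the n×n covariance is the well-estimated side. It
alternates re-estimating the line covariance from the completed matrix with
replacing each missing entry by its conditional expectation given the other
lines' observed genotypes at that marker (one n×n precision inverse per
sweep, then a missing-block solve per column). Two numerical points:
(i) because each column is centered by its own observed mean, the observed
residuals per column sum to exactly zero, planting an artificial null
direction along **1** in the sample covariance that a naive conditional
exploits ("this line equals minus the sum of the others"); the covariance
therefore includes a rank-one term `c·11′` with `c = avg var / mean n_obs`,
modelling the sampling error of the per-marker means. (ii) convergence of
the iterated conditional is geometric but slow; defaults are tol 10⁻⁴ on
imputed entries and 100 iterations, with a warning (not an error) and the
best iterate returned on non-convergence — masked-entry accuracy is
insensitive to the late iterations. A line duplicating a complete line is
restored essentially exactly, and on masked DH data EM roughly halves the
masked-entry RMSE relative to mean imputation.

## Problem sizes and tolerances in the tests

The verification suite runs at desk scale as the package's own choice of
study conditions: populations of 40–500 lines with a few hundred to a few
thousand markers, 20-seed batches for directional claims (EM vs mean,
within- vs cross-year, BLUP-trained vs cross-year), 3-seed pooled profiles
for the thinning plateau. Exact oracles (ridge equivalence, brute-force G,
balanced-design BLUPs, the d̄ hand enumeration) are asserted at 10⁻⁶ or
tighter; Monte-Carlo comparisons at 3 batch-means SEs; simulation
recoveries at the tolerance the sampling variance of the configuration
supports (e.g. mean ĥ² within ±0.1 of 0.5 over 20 datasets of n = 200).
`scripts/acceptance.py` re-runs the headline computations on a 257-line,
600-marker population (10 chromosomes × 60 markers) in a few minutes;
marker counts are reduced relative to a real 14k-SNP GBS panel because the
methods' behavior, not their throughput, is under test.

## Known limitations

- REML for the two-way G×E model relies on statsmodels' optimizer; on
  degenerate data (no replication) the interaction variance is fixed at 0
  rather than estimated.
- The Gibbs sampler uses a single kernel; kernel averaging and Bayesian
  bandwidth selection are out of scope.
- Marker thinning has no map-based variant (the emulated SNP build has no
  positions); only correlation-based pruning is provided.
- `p_i` for G is computed from all supplied lines; a per-fold re-estimation
  switch is not exposed because candidate genotypes carry no phenotype
  information, but analyses that subset lines *after* building G should
  rebuild it.
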