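# Methods

This note documents the statistical models behind `rhizolink`, the
design decisions taken where several defensible options existed, and
what the synthetic benchmarks do and do not demonstrate.

## The discovery problem

Given 16S amplicon sequence variant (ASV) counts from rhizosphere
samples and continuous plant-growth measurements from the same pots, the
pipeline asks which community features (single ASVs, linear combinations
of ASVs, or co-occurrence modules) predict growth, while controlling for
the spatial block structure of a greenhouse experiment. Associations are
correlative by construction; the pipeline's job is to make the reported
set small, signed, and stable.

The pipeline has five inferential stages:

1. **Compositional preparation.** Counts are relative; all regression
   inputs are centered log-ratio (CLR) transformed. For each association
   test the feature set is first restricted by abundance rank and
   prevalence (top 200 by mean relative abundance, then a prevalence
   floor), the excluded features are pooled into a single remainder part
   so the composition stays closed, and a pseudocount is added before
   logs. Each test runs under a loose and a strict prevalence preset
   (defaults 0.3/0.5 loose and 0.5/0.9 strict for disrupted/inoculated
   communities); a feature is a candidate if selected under either, with
   a flag recording agreement.
2. **Stability-selected LASSO.** An L1-penalized Gaussian regression of
   the growth response on the CLR matrix, with the penalty chosen per
   run by k-fold cross-validated MSE over a 100-point log-spaced path.
   The path floor follows the reference-tool convention: 0.01 of the
   fully-shrinking penalty when n < p, 1e-4 otherwise (a fixed deeper
   floor wastes the path on hopelessly overfit penalties and coarsens
   the grid near the CV optimum). Predictors are standardized and the
   intercept unpenalized. The fit is repeated `n_runs` times (default
   100) and a feature is *selected* when its coefficient is nonzero in
   at least `threshold` runs (default 80).
3. **Bayesian hierarchical confirmation.** Each candidate is refit in a
   Gaussian linear mixed model with a random intercept and a random
   slope per block; a feature survives when the central 95% credible
   interval of its population slope excludes zero.
4. **Multivariate refinement.** All candidates of a test enter one
   hierarchical model which is pruned by greedy backward elimination
   under PSIS-LOO expected log predictive density (drop the feature
   whose removal most improves, or least harms, ELPD; stop when the best
   removal is worse than the current model by more than one standard
   error of the pointwise ELPD difference). Features significant only in
   the multivariate context are reported distinctly from univariate
   survivors.
5. **Permutation screen.** Response values are permuted within each
   test's samples, the entire selection procedure is rerun with
   identical settings, and every real association is removed from any
   test whose scrambled run still confirms more than one feature. The
   screen is deliberately conservative and never adds associations.

## Run-to-run variation in stability selection

Cross-validated LASSO is rerun with re-randomized fold partitions *and*
a fresh 80% row subsample per run. Fold randomization alone cannot
control dataset-level chance correlations: at n = 60 and p > 100 the
largest chance |r| is ~0.4, and such a feature reduces CV error in
every fold partition of the same dataset, so it would be "stably"
selected no matter how folds are drawn. Subsampling rows (the device of
stability-selection theory) makes such features unstable while leaving
genuinely predictive features selected in essentially every run.
Measured at n = 60, p = 120 with 25 runs and a 20/25 threshold: a
feature explaining 30% of response variance is selected in >90% of
datasets, while under a global null fewer than 15% of datasets select
anything. Set `subsample_frac: null` to fall back to fold randomization
only.

## The hierarchical model

For response `y_i` with feature values `x_ij` and block `b(i)`:

    y_i = b0 + sum_j b_j x_ij + u_{b(i)} + sum_j v_{b(i),j} x_ij + e_i
    e_i ~ N(0, sigma^2); u_b ~ N(0, tau_0^2); v_{b,j} ~ N(0, tau_j^2)

Priors scale with the data: `b0 ~ N(mean(y), (2.5 sd(y))^2)`,
`b_j ~ N(0, (2.5 sd(y)/sd(x_j))^2)`, `sigma^2 ~ InvGamma(2, var(y))`,
and half-t(2) priors on every random-effect SD via the Huang–Wand
inverse-gamma parameter expansion (scale `sd(y)` for the intercept SD,
`sd(y)/sd(x_j)` for slope SDs). All conditionals are then conjugate and
posterior draws come from a blocked Gibbs sampler that draws the entire
location vector (fixed plus random effects) jointly from its
multivariate-normal conditional — the mixing-critical step — followed by
scalar variance updates. Defaults are 2 chains x (500 warmup + 1000
draws); convergence is flagged via split R-hat (limit 1.05) and
non-converged fits are excluded from the credible gate.

R-squared follows the Bayesian posterior-predictive definition
(`var(fit) / (var(fit) + sigma^2)` per draw, then averaged): *marginal*
uses the fixed-effect fit only, *conditional* adds block effects. LOO
uses Pareto-smoothed importance sampling on the pointwise log-likelihood
draws.

Calibration, not convention, is the contract: simulating repeatedly from
the model itself (6 blocks, n = 60), nominal 95% intervals cover the
true slope at close to nominal rate, and the credible gate fires on
zero-slope data well below 10%. The acceptance suite re-measures both.

## Co-occurrence networks

Per sample group (treatment x time stage), features detected in at least
4 samples with mean relative abundance above 0.5% are CLR-transformed
and passed to the graphical lasso over a 20-point log-spaced penalty
path whose floor is 0.01 of the largest absolute off-diagonal
covariance. The penalty is selected by StARS: edge-selection frequencies
over 50 random 80% subsamples give a per-penalty instability
`mean(2 theta (1-theta))`; walking from sparse to dense, the selected
penalty is the last one before the monotonized instability exceeds 0.05.
(The walk stops at the first crossing, so the expensive dense tail of
the path is never fitted.) Edges are the nonzero off-diagonal entries of
the penalized precision at the selected penalty; edge weights are the
correlations implied by the estimated covariance (`cov2cor`), restricted
to selected edges.

Modules are Louvain communities of the positive-edge graph (negative
edges removed first; isolated vertices become singletons; the vertex
ordering is seeded so reruns are identical). Per-vertex *strength* is
reported both as the signed sum of incident weights and as the sum of
absolute weights; the absolute-sum version is the headline, since signed
sums can be near zero for vertices with balanced positive and negative
edges while printed strengths in this literature are positive.
Quartile subnetworks keep edges whose weight exceeds the third quartile
or falls below the first quartile of the *full* network's weight
distribution, restricted to growth-associated vertices and their strong
neighbors; growth-associated vertices without strong edges are listed
separately. Module abundance tables (per-sample sums of member-feature
counts) feed back into the same selection pipeline, with modules present
in fewer than 27% of samples omitted (configurable).

## The synthetic generator

The generator emulates a two-treatment greenhouse time series: 6 spatial
blocks, harvests on days 2–14 with five-times-daily sampling during the
early (days 3–4) and late (days 13–14) windows, one destructive
rhizosphere sample per pot, 60 samples per treatment x stage group.

* **Growth** is exponential on the log projected-area (PA) scale with
  per-treatment intrinsic rates (defaults 0.33/0.30 day⁻¹ inoculated /
  disrupted — fast-cycling Brassica values with a modest inoculation
  benefit), block and pot rate perturbations, and lognormal measurement
  noise; biomass is proportional to PA at harvest with lognormal error.
  Pre-dawn harvests roll to the next calendar date so collection date is
  not collinear with days grown in the residual regressions.
* **Counts** follow a logistic-normal multinomial: latent log-abundances
  are multivariate normal with a block-diagonal sparse precision
  (modules), feature-level means spread with SD 1.2 (the rank-abundance
  curve), and additive log-scale shifts (default 1.0) for designated
  block-, stage- and treatment-biomarker features; counts are
  multinomial at exactly `depth` reads (default 2,000 at the default
  desk scale of 150 features).
* **Module topology** is a circulant ring-with-chords graph per module
  (degree 4, partial correlation ~0.2 by default). Circulant expanders
  have no cheap cuts, so a planted module is a single community under
  modularity optimization when its edges are recovered — random regular
  graphs of the same degree are provably split by resolution-1
  modularity even when fully recovered.
* **Growth couplings** are planted at the response level: for each
  planted (feature, group, response), the response equals a baseline
  plus `slope x latent CLR(feature)` plus block intercepts (20% of the
  noise variance) plus Gaussian noise, with the noise variance solved
  analytically from the latent CLR covariance so the planted features
  jointly explain a target share of response variance (default 30%).
  Growth is generated *from* features, matching the direction of the
  downstream regression. Planted features are assigned top-quantile mean
  abundances (by swapping feature means) because discoverable features
  must clear the rank/prevalence filter, and low-abundance features
  suffer multinomial attenuation of their CLR signal. By default planted
  features are module *singletons* (`planted_in_modules=False`): a
  feature planted inside a correlated module would make its module-mates
  genuinely marginally associated with the response, leaving the ground
  truth ill-defined for recovery benchmarks; set the flag to study
  exactly that regime.

What the generator does **not** emulate: sequence-level error (no reads,
chimeras or taxonomy), 16S copy-number variation, uneven sequencing
depth, overdispersion beyond the logistic-normal, temporal
autocorrelation within a pot (each pot is sampled destructively once),
and any feedback from plant growth to community composition. Passing
benchmarks therefore demonstrate correctness of the statistical
machinery under its own assumptions, not performance on real rhizosphere
data.

## Benchmark problem sizes

The acceptance suite and `scripts/acceptance.py` use deliberately scaled
conditions. Stability operating characteristics: 25 runs with a 20/25
threshold, 10-fold CV, 50 replicate datasets, with the signal feature
explaining exactly 30% of the realized sample variance (signal and
orthogonalized noise rescaled), so the measurement reflects power at the
stated operating point rather than sampling variation of the effect
size. Sampler calibration: 200 datasets at 1 chain x 500 draws.
End-to-end recovery: 150 features, depth 2,000, five planted couplings
(three positive, two negative, 30% target R²), with the association
suite run over exactly the five tests carrying those couplings at the
full 100-run/80 stability setting with 5-fold CV; all-null test grids are exercised by
the separate permutation-screen benchmark (20 null experiments).
Network recovery: 60 features, three modules, n = 200, depth 25,438,
30 StARS subsamples. These sizes keep a complete desk run reproducible
while preserving each method's operating regime.

## Known limitations

* The permutation screen uses one scrambled replicate by default (more
  are configurable); single-replicate screens are noisy and can remove
  genuinely coupled tests when a scrambled run fires by chance.
* At the desk-scale group size (n = 60) with ~130 candidate features per
  test, the expected maximum chance correlation within a test is ~0.4 —
  at the boundary of what a 95% credible gate detects — so each
  association test carries an appreciable probability (~0.3–0.6) of
  reporting one chance feature alongside any true one. This is a
  property of the method at these dimensions, not of the
  implementation; the permutation screen removes whole tests that fire
  under scrambling but cannot remove a single chance passenger inside a
  genuinely coupled test.
* Resolution-1 modularity genuinely prefers to split sparse 20-vertex
  modules of a recovered network when a few edges are missed (the gain
  is small but real); perfect module agreement should not be expected
  from glasso support graphs whose partial correlations sit near the
  positive-definiteness limit of sparse all-negative precision blocks.
* CSS normalization implements the published cumulative-sum-scaling
  definition with an adaptive percentile modeled on the reference
  procedure (median-deviation profile across samples, relative-change
  rule, floor 0.5); a fixed percentile can be supplied for exact
  reproducibility.
* The Gibbs sampler covers Gaussian responses only, which is all this
  pipeline needs.
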