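# Methods

## Model

`glvinfer` models an ecosystem of L taxa by the extended generalized
Lotka-Volterra (gLV) equations. The concentration f_l of taxon l in one
subject evolves as

    df_l/dt = alpha_l f_l + sum_j beta_lj f_l f_j + sum_p gamma_lp f_l u_p(t)

with growth rates alpha_l (1/day), pairwise interaction coefficients
beta_lj (1/(day·concentration)), perturbation effects gamma_lp (1/day),
and binary on/off indicators u_p(t) for experimental perturbations
(diet shifts, antibiotics). Constrained inference enforces the
biologically motivated signs alpha_l > 0 and beta_ll < 0 (logistic growth
to a finite carrying capacity in the absence of interactions). The model's
key assumptions: interactions are pairwise and time-invariant, perturbation
effects act multiplicatively on per-capita growth, and measured fecal
concentrations proxy for the ecosystem state.

Sequencing counts constrain only relative abundances; a per-sample
total-biomass measurement (e.g. universal 16S qPCR) restores the absolute
scale. Both inputs are first converted into concentration trajectory
estimates f-hat and gradient estimates f-hat′, after which parameter
inference is *gradient matching*: because every gLV term carries an f_l
factor, regressing f-hat′ on (f-hat, f-hat·f-hat_j, f-hat·u_p) is a linear
problem that decouples into one block per target taxon. This avoids
repeated numerical integration during fitting; integration is used only
for forecasting and downstream analyses. A log-space variant (each row
divided by f-hat, regressing per-capita growth) is available via
`build_gradient_match_system(log_space=True)`; the two agree exactly on
noise-free data but weight noise differently.

## Trajectory estimators

**First-order differences** (`finite_difference_estimate`): f-hat at the
sample days is relative abundance × biomass; gradients are forward
differences over the (possibly irregular) spacing, with a backward
difference at the final day. Fast and assumption-free, but count noise
passes straight into the gradients.

**Negative-binomial penalized splines** (`fit_bapcs`): a Bayesian smoother
tailored to sequencing data. Per subject, each taxon's log concentration
is a clamped cubic B-spline with breakpoints every 2 days (default);
counts are negative-binomial with mean = read depth × compositional share
of the latent curves and per-taxon dispersion r_l; log biomass is Gaussian
around the log of the latent total with variance sigma_w². The log link
makes positivity structural, which the NB mean requires anyway. Smoothness
is imposed by an adaptive Bayesian lasso — a Laplace scale-mixture prior on
first-order coefficient differences (second-order available by config)
with one learned rate per (taxon, subject) and one local scale per
coefficient difference — so flat stretches are shrunk hard while real
excursions are kept. Dispersions share a hierarchical lognormal prior
across taxa (a mean-trend model in the style of count-based differential
expression tools is deliberately not fitted: with 10-13 taxa there is no
support for a trend). Sampling is Metropolis-within-Gibbs: random-walk
updates for spline coefficients (proposal scales adapted toward 44%
acceptance during burn-in), conjugate updates for the scale mixture, the
lasso rates, the biomass variance and the dispersion hyper-mean, and a
log-scale random walk for each r_l.

Default chain schedule: 25,000 iterations, 2,500 burn-in, thinning 20,
retaining 1,125 draws; a seed is mandatory. Reported trajectories use the
elementwise posterior-median spline coefficients, so the reported gradient
is exactly the analytic derivative of the reported curve (chain rule
f′ = f · d(log f)/dt); per-point posterior standard deviations are
reported separately as `spread`. Taxa with fewer than 4 positive counts in
a subject are excluded there and reported as zero (they also contribute no
gradient-match rows). A convergence summary (split-chain R-hat on the
log-likelihood trace) is recorded as a warning, never silently acted on.

Dense output grid step: 0.25 day. Zero counts are ordinary NB
observations; no pseudocounts. The level of each log-spline is weakly
anchored (sd 10 in log units) at its initialization — a penalized
least-squares fit to the empirical concentrations — which matters only
when biomass is missing for most of a subject's samples.

`interpolate_biomass` refits the smoother using whatever biomass is
present (≥ 4 anchors per subject required) and fills missing values with
the posterior-median fitted total. Accuracy degrades as more biomass is
hidden; the operation itself does not police that.

## Parameter inference

All four fitters consume the same gradient-match blocks.

**MLRR** — per-taxon ridge regression in closed form. The penalty is
diagonal with two values: one shared by the growth and perturbation
columns, one for the interaction columns (the minimal structure consistent
with "regularization parameters", plural). `select_lambda_cv` picks them
by leave-one-subject-out forecast RMSE on log10 concentrations over a
log-spaced grid (default 10⁻³…10³) — forecasting is the end use, so it is
also the selection criterion; with a single subject it falls back to
holding out the later half of the time grid, with a warning.

**MLCRR** — the same objective with alpha_l ≥ ε and beta_ll ≤ −ε
(ε = 10⁻⁵ buffers the open constraints). Each block is a bound-constrained
least-squares problem (penalty folded in as augmented rows) solved by BVLS;
KKT conditions of the returned solution are verified to 10⁻⁶.

**BAL** — Bayesian adaptive lasso. Gaussian residual likelihood per block
with per-taxon variance; Laplace scale-mixture priors on off-diagonal
interactions and perturbation effects with a per-target-taxon rate learned
from the data; truncated-normal priors (scale 10) keep alpha_l positive
and beta_ll negative. Full Gibbs: coordinate-wise truncated/plain normal
updates, inverse-Gaussian scale updates, gamma rate updates,
inverse-gamma variance updates.

**BVS** — spike-and-slab variable selection. Each off-diagonal interaction
and perturbation effect carries a Bernoulli indicator with prior inclusion
probability pi0 (default 0.5, config-exposed; this makes a Bayes factor
equal the posterior odds); conditional on inclusion the coefficient has a
zero-mean normal slab whose variance follows an inverse-gamma hierarchy.
Indicators are updated with the coefficient marginalized, so absent edges
are exactly zero in every draw. Growth and self-interaction are always
included, with the same truncations as BAL.

Both samplers default to the 25,000 / 2,500 / 20 schedule (1,125 retained
draws); burn-in length is a package choice. Convergence is monitored by
split-chain R-hat on each block's growth-rate trace and logged.

**Edge evidence.** Posterior inclusion probabilities convert to Bayes
factors BF = posterior odds / prior odds, computed from inclusion *counts*
so the conventional strong-evidence boundary BF = 10 is exact. A
probability of exactly 1 over n draws is reported as the capped lower
bound n·(1−pi0)/pi0 with a cap flag. Network scores for ranking: BVS →
inclusion probability; BAL → |posterior-median beta|; MLRR/MLCRR →
|beta-hat|; the Spearman baseline → pooled |rank correlation| of
concentration series, copied to both directed orientations.

## Ecological analyses

An interior steady state of a sub-community solves
beta_sub x* = −(alpha_sub + active-perturbation adjustment); it is
*feasible* if all components are strictly positive and *stable* if every
eigenvalue of the Jacobian diag(x*)·beta_sub has negative real part.
Singular sub-matrices are flagged "degenerate", distinct from infeasible,
and excluded from stable counts. `enumerate_subcommunities` screens all
2^L − 1 subsets (hard cap L ≤ 20) across posterior draws and keeps those
whose fraction of feasible-and-stable draws exceeds a threshold (default
0.9); extra thinning of retained draws is available for large
enumerations.

Invasion challenges initialize the commensals at each draw's own steady
state (not a shared median profile), add the invader at the requested
dose, integrate the joint system to the horizon, and report the median and
median absolute deviation of the invader's final concentration across
draws; draws that blow up are excluded and counted.
`rank_exclusion_communities` returns, per community size, the stable
community minimizing the median invader concentration, with median ties
broken by higher stability probability.

Keystoneness starts from the largest sub-community above the stability
threshold (ties: higher stability probability, then lexicographic),
removes each member in turn, recomputes the reduced steady state per draw,
and reports Ky = the Euclidean distance between baseline and reduced
steady states over the surviving taxa only (median across draws where both
are stable). Removals that leave no stable configuration are reported as
such with Ky = NaN. `compare_regime_biodiversity` applies a two-sample
Wilcoxon rank-sum test (exact for small counts) to the coexisting-taxon
counts of two regimes' stable states.

## Simulation benchmark

`generate_ground_truth` rejection-samples 10-taxon systems (one designated
invader): growth ~ LogNormal(log 0.2, 0.4²) per day, self-interaction
~ −LogNormal(log 0.5, 0.3²), each off-diagonal interaction present with
probability 0.20 and drawn N(0, 0.15²). A candidate is accepted when (i)
the full community has a feasible interior steady state and (ii) across
20 random initial conditions, at least 75% of integrations give every
taxon a trajectory coefficient of variation above 0.25 — a system pinned
at equilibrium carries no inferential signal. Initial conditions are
displaced from the steady state by a factor exp(±U(1.5, 2.5)) per taxon
(direction random). The displacement floor is deliberate: multiplicative
perturbations that can land arbitrarily close to equilibrium produce
near-flat trajectories whose CV is analytically capped near the filter
threshold, making the filter vacuous or unattainable; well-displaced
starts emulate colonization-style experiments where sampling begins far
from equilibrium. All scale hyperparameters are calibrated by simulation
(real-data-derived values are not available) and config-exposed.

`simulate_dataset` integrates each subject from its own displaced start,
doses the invader at day 10 (default 0.1 × steady-state total mass),
samples the design days (27/18/12/8 points over 30 days, or any count),
draws counts from a Dirichlet-multinomial (concentration parameter 50 by
default, giving visibly super-multinomial dispersion at depth 1,000) and
biomass from a Normal on log10 with sd 0.1. The DMD is deliberately a
*different* noise family (compositional, jointly overdispersed) than the
NB the smoother assumes, so benchmark results measure robustness, not
self-consistency.

Metrics: growth-rate RMSE, interaction RMSE, directed-network AUC
(midrank ties; NaN for single-class truth), and hold-one-subject-out
forecast RMSE on log10 concentrations with a floor of 10⁻¹⁰ × the maximum
observed concentration. The study-design guideline
`recommend_min_timepoints(L, S)` returns ceil((L²/2)/S) samples per
subject.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run scaled-down configurations
chosen to exercise every code path at meaningful signal-to-noise: MCMC
chains of 1.2k-4k iterations on 1-5 subject fixtures, 20-replicate
benchmark batches, 3-5 taxon systems for dynamical cross-checks. The
full-scale defaults (25k iterations, 400-replicate benchmarks) are the
package defaults and run unchanged, just longer.

## Known limitations

* Only pairwise interactions and binary perturbations; no metabolite,
  immune or higher-order terms.
* Gradient matching inherits bias from the trajectory estimator; with
  very sparse sampling the smoother's shrinkage can flatten fast
  transients and the first-order-difference estimator is noisy.
* The synthetic generator emulates overdispersed compositional counts,
  subject-to-subject initial-condition variability and irregular designs;
  it does not emulate taxon dropout across subjects, measurement batch
  effects, day-to-day biomass drift unrelated to the community state, or
  phylogenetically structured interaction networks. Passing benchmarks
  therefore demonstrate correctness of the machinery and robustness to
  compositional noise, not performance on any particular real ecosystem.
* Maximum-likelihood confidence intervals are intentionally not provided;
  use the Bayesian fitters for uncertainty.
* The posterior-median-coefficient trajectory summary trades a small
  amount of pointwise optimality for an exact trajectory/gradient
  consistency identity.
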