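# Methods

## The model

A clade's unknown species richness through time is represented on a grid
of half-open 1-Myr bins (`[i, i+1)` Ma, bin 0 most recent; bin width is
configurable). Latent log richness follows a Gaussian random walk with
variance `sig2` per Myr — a Brownian bridge once both endpoints are
pinned. The origin endpoint is one lineage (log richness 0) in the bin
containing `t_origin`. For extant clades the other endpoint is the
present-day richness `log(n_extant)` in bin 0; for extinct clades it is
one lineage in the bin containing the extinction time `t_ext`, with
richness zero in all younger bins. A clade must pass through a single
lineage on its way out, and log 0 is undefined, so pinning the terminal
bin at one lineage is the natural discrete analogue of "diversity
constrained to zero at extinction". `t_ext` has support between the
present and the youngest fossil; `t_origin` between the oldest fossil and
a configurable cap (default 600 Ma, comfortably predating any plausible
mammalian clade).

Sampled richness per bin is Poisson:
`c_i ~ Poisson(exp(x_i) * p_i)` with `p_i = 1 - exp(-q(t_i))` at the bin
midpoint `t_i`, which converts a per-lineage per-Myr recovery rate into a
per-lineage detection probability and is well-behaved for rates above 1.
The rate rises exponentially with elapsed time,
`q(t) = q0 * exp(a (t_origin - t)/t_origin)`, so `q0` is exactly the rate
at origination and `q0 * exp(a)` the rate at the present. The exponential
form and the Poisson count model are modelling choices (the count
distribution is not dictated by the latent-trajectory formulation); both
are isolated behind `sampling_rate_at` / `log_sampling_lik` so alternates
can be swapped.

Two support constraints are enforced as −inf log posterior: latent
richness at least one lineage in every bin of the lifespan (for extant
clades this is "cannot go extinct before the present"; we apply it to
extinct clades too — richness below one lineage means the clade is already
gone), and latent richness at least the sampled richness in every bin.

Priors: `t_origin` and `t_ext` uniform on their supports; `q0` and `sig2`
exponential with mean 1; `a` exponential with mean 10. All are weakly
informative on the scales of family-level data (rates of order 0.001–1,
bridge variances of order 0.1–2) and configurable via `PriorConfig`.

The bridge density is written as the product of per-bin Gaussian
increments with the endpoints held fixed; no explicit endpoint-conditioning
normalizer is included. Because that normalizer varies with the span
length (as `span^(-1/2)`), omitting it tilts the origin marginal very
slightly toward shorter lifespans; the effect is second-order relative to
the likelihood penalty of empty extension bins (which grows linearly in
the number of bins), and the simulation study shows no measurable bias.
The prior-only sampling mode used in the tests does include the
normalizer, so that the latent path integrates out exactly and the chain
must reproduce the uniform prior on `t_origin` — a sharp correctness check
on the dimension-changing moves.

## MCMC

One iteration is a deterministic-scan sweep of Metropolis–Hastings block
updates: sliding-window moves of `t_origin` and `t_ext` (with a 10%
chance of an independence jump across the whole prior support, which lets
chains cross long fossil-free gaps); multiplier moves of `sig2`, `q0`,
`a`; and five re-draws of random trajectory windows (1–10 bins; 15% of
the time up to 80 bins) from the exact Gaussian-bridge conditional given
their flanking values, accepted on the sampling-likelihood ratio alone.

When an origin or extinction move crosses a bin boundary the trajectory
changes dimension; the newly exposed bins receive fresh values proposed
sequentially from Gaussian steps anchored at the new pinned endpoint, and
the acceptance ratio carries the proposal density of the added (or
deleted) values — a reversible-jump birth/death correction.

Three extra moves target the posterior's slow ridges, each preserving the
target exactly:

* **level shift**: all interior log-richness values moved together
  (richness level vs bridge edge terms);
* **level–rate ridge**: `x + delta` with `q0 * exp(-delta)` — the Poisson
  means are nearly invariant along this direction, which otherwise limits
  the rate parameters to the speed of path-level drift;
* **trend ridge**: a multiplier on `a` with `q0` compensated so `q` is
  unchanged at the count-weighted mean elapsed-time fraction;
* additionally `sig2` alternates multiplier steps with draws from its
  inverse-gamma conditional given the path increments, and a non-centered
  rescale move scales path deviations jointly with `sig2`.

Proposal scales are tuned toward 0.2–0.4 acceptance during burn-in
(default 20% of the run) and frozen afterwards, preserving detailed
balance for the retained samples. Retained samples are thinned (default
every 100 iterations); an optional early stop ends the run once every
logged parameter passes the effective-sample-size rule (ESS > 100).
Chains are exactly reproducible given the seed, and per-family seeds are
derived by hashing the global seed with the family name, so adding or
removing one family never changes another's results.

For speed the sampler tracks the prior, bridge and likelihood terms
separately and recomputes only what a move can change (window-local
likelihood deltas for trajectory moves, closed-form bridge-edge deltas for
shifts); caches are rebuilt from scratch every 2,000 iterations, and an
`audit` mode asserts at each rebuild that the incremental likelihood
matches a scratch recomputation. The density kernels are numba-compiled;
the same quantities are also implemented directly from the model
definitions in `bbb_core`, and the test suite asserts exact agreement
between the two routes on randomized states.

Point estimates are posterior medians (means are stored alongside);
intervals are 95% highest-posterior-density intervals. The ESS estimator
sums the initial positive sequence of autocorrelation pairs (monotone
enforced) with a Sokal-style window cap of five autocorrelation times —
calibrated in the tests against iid draws and an AR(1) chain with known
integrated autocorrelation time.

### Convergence bookkeeping at the two protocol scales

The convergence rule, minimum ESS above 100 across logged parameters, is
defined for empirical runs of 1,000,000 iterations. At the
simulation-protocol length of 50,000 iterations the slowest parameter
(usually the trend exponent `a`, integrated autocorrelation time of order
10³ sweeps) typically reaches ESS 5–50, while the origination and
extinction ages reach 30–500; extrapolated to the empirical length the
rule is met. Simulation-scale validation therefore flags and excludes
only clearly stuck chains (min ESS below 10), and the interval-coverage
check, which measures calibration rather than convergence, includes all
replicates.

## The simulator

The validation generator draws, per dataset: origination `U[100, 600]` Ma;
extinction `U[10, 0.9 * t_origin]` Ma; a true-richness path; per-bin
sampling rates `Exponential(mean 0.0067)` — about one fossil per 150
standing lineages per bin — modulated by a mean-preserving linear doubling
toward the present; and a fraction `U[0.1, 0.5]` of bins forced to rate
zero, emulating barren intervals of the rock record. Counts are Poisson;
bins whose draw exceeds the true richness floor are redrawn so simulated
data always satisfy the model's support constraint, and an all-zero
dataset is redrawn entirely.

The richness path is a random-walk **excursion**: a Gaussian random-walk
bridge rotated at its minimum (the Vervaat construction), which leaves one
lineage, stays positive, and returns to one lineage — a wax-and-wane
history. The excursion is rescaled so its peak equals a per-dataset
standing richness drawn lognormally with median 1,000 species and log-sd
0.7. That scale was calibrated once, against a single statistic of the
generated records and before any inference was run: with it, the mean
fraction of fossil-free lifespan bins across datasets is ≈51% (per-dataset
range ≈18–88%), the regime of real family-level records, and consistent
with the one-in-150 arithmetic above (a raw log-scale bridge pinned at one
lineage cannot reach this regime at any walk variance — half of such a
path sits at the one-lineage floor, leaving 80–90% of bins empty). Because
of the peak rescaling the excursion's shape is scale-invariant in the walk
variance `sig2_sim`; the parameter is retained for its zero-variance limit
(richness identically one lineage).

What the generator does **not** emulate: taxonomic error and synonymy,
age-model uncertainty in bin assignment (collections are binned at known
ages), spatially structured sampling, correlated preservation between
adjacent bins, and diversification histories outside the
excursion-with-one-peak family (e.g., multiple radiations). Passing the
recovery tests therefore shows the estimator works when the record is a
noisy thinning of a smooth richness history with gaps — not that it is
robust to systematically biased taxonomy or dating.

Estimator accuracy is scored as signed relative error
`(estimate − truth)/truth` of the posterior medians, with interval sizes
and 95%-HPD coverage reported alongside. The desk-scale recovery test
(30 datasets, 50,000 iterations) asserts absolute mean relative errors
below 0.06 for the origination age and 0.15 for the extinction age and
signed errors within two standard errors of zero; in our runs both
absolute means land near 0.01.

## Stratigraphic comparator

The classical uniform-recovery confidence interval extends a family's
stratigraphic range `R` (oldest minus youngest horizon age, horizons =
unique fossil collections) by `alpha = R ((1-C)^(-1/(H-1)) - 1)`. The
origin interval runs from the oldest horizon back by `alpha`; the
extinction interval forward from the youngest horizon, floored at the
present (the flooring convention is ours). `H < 2` is an error — one
horizon carries no information about recovery density. Nonuniform-recovery
generalizations are out of scope.

## Numerical choices and degenerate inputs

* Initialization: `t_origin` at the oldest fossil + 5 Myr, `t_ext` at half
  the youngest fossil age, scalar parameters at their prior means, and the
  trajectory as the linear interpolation of the pinned endpoints lifted to
  the sampled-richness floor. If the posterior is not finite there, up to
  1,000 random restarts are attempted before erroring.
* Support tolerances: the richness-floor constraint is checked with a
  relative slack of ~1e-12 so `exp(log(c))` round trips never reject a
  valid state; the same tolerances are shared by the incremental and
  scratch likelihood paths.
* An extinct family whose most recent bin holds two or more species admits
  no valid extinction time inside that bin (the terminal pin is one
  lineage); such inputs fail at initialization with a clear error. In
  practice recently extinct species in the most recent bin are treated as
  extant diversity upstream.
* Ages exactly on a bin boundary belong to the younger-indexed bin
  (half-open convention); collection ages are drawn once per collection,
  uniform in the reported interval, in order of first appearance.
* A record failing several cleaning filters is tallied once, under the
  first failing rule (no family, no species, age range > 20 Myr, trace
  fossil), since only totals are ever reported.
* `n_extant` is taken as supplied; recently extinct species counted in
  bin 0 are not reconciled against it.

## Known limitations

* Single-clade analyses only: no joint models with sister-clade
  constraints, and no birth–death likelihood (the trajectory model
  deliberately integrates over diversification histories instead).
* The trend form is monotone; preservation histories with mid-span maxima
  are absorbed by the latent trajectory rather than the rate.
* The ESS rule is a single-chain diagnostic; no multi-chain R-hat is
  computed.
* At simulation-scale chain lengths the trend exponent mixes slowly
  (see above); headline age estimates are unaffected, but `a` posteriors
  from short chains should be read with care.
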