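# fossilbridge

Bayesian estimation of when a clade originated — and, for extinct clades,
when it died out — from its binned fossil record alone.

Molecular clocks and fossil-calibrated phylogenies give one reading of
clade ages; the fossil record itself gives another, but it cannot be read
literally: a lineage must exist before its first preserved fossil, and
preservation is patchy and improves toward the present. `fossilbridge`
implements a probabilistic interpretation of the record for paleobiologists
working with occurrence data (e.g., Paleobiology Database exports at family
level, as in the placental mammal radiation debate around the K-Pg
boundary): it treats the unknown true species richness of a clade through
time as a latent trajectory and infers the time at which that trajectory
hits a single lineage.

## Model

Time runs in discrete bins of width 1 Myr, indexed from the present. The
latent log richness `x_i` follows a Brownian bridge with variance `sig2`
per Myr, pinned at one lineage (`x = 0`) in the bin containing the
origination time `t_origin`, and at the other end pinned at the
present-day richness `log(n_extant)` (extant clades) or at one lineage in
the bin containing the extinction time `t_ext`, after which richness is
zero (extinct clades; `t_ext` is estimated between the youngest fossil and
the present). Observed counts of sampled species per bin are

```
c_i ~ Poisson( exp(x_i) * (1 - exp(-q(t_i))) ),
q(t) = q0 * exp( a * (t_origin - t) / t_origin ),
```

where `q0` is the per-lineage per-Myr sampling rate at origination and the
trend exponent `a >= 0` lets preservation rise exponentially toward the
present. Two hard constraints apply: a living clade never has fewer than
one lineage, and latent richness never drops below the sampled richness of
any bin. Everything — `t_origin`, `t_ext`, `sig2`, `q0`, `a`, and the
latent trajectory (by data augmentation) — is sampled jointly with
Metropolis–Hastings; the accompanying classical comparator computes
Marshall-style stratigraphic confidence intervals
(`alpha = R * ((1-C)^(-1/(H-1)) - 1)`) from horizon counts.

## Worked example

```python
import numpy as np
from fossilbridge import BinnedCounts, MCMCConfig, run_mcmc, summarize_trace
from fossilbridge.simulator import simulate_clade

clade = simulate_clade(np.random.default_rng(3))  # extinct clade, known truth
print(f"truth: origin {clade.true_t_origin:.1f} Ma, extinction {clade.true_t_ext:.1f} Ma")

trace = run_mcmc(clade.counts, MCMCConfig(n_iterations=50_000, thin=10, seed=5))
est = summarize_trace(trace, clade.counts)
print(f"origin     {est.root_est:.1f} Ma, 95% HPD [{est.root_lower:.1f}, {est.root_upper:.1f}]")
print(f"extinction {est.ext_est:.1f} Ma, 95% HPD [{est.ext_lower:.1f}, {est.ext_upper:.1f}]")
```

prints

```
truth: origin 142.8 Ma, extinction 38.1 Ma
origin     147.7 Ma, 95% HPD [142.0, 162.3]
extinction 39.8 Ma, 95% HPD [32.4, 43.0]
```

The point estimates are posterior medians; the intervals are the narrowest
95% highest-posterior-density ranges. Here both true ages fall inside
intervals ten to twenty Myr wide — the typical scale on simulated extinct
clades — whereas the classical stratigraphic interval for a family with
few fossil horizons can span hundreds of Myr.

A command-line interface covers the full pipeline — cleaning and binning a
PBDB export, per-family analysis, simulation, validation, stratigraphic
intervals and clade summaries:

```
fossilbridge clean --pbdb occurrences.csv --modern modern.csv --out binned.csv
fossilbridge analyze --counts binned.csv --iterations 1000000 --outdir results/
fossilbridge stratci --pbdb occurrences.csv --out strat.csv
fossilbridge summarize --traces results/ --clades clades.csv --out clade_probs.json
```

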