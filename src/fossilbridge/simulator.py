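"""Simulation of extinct-clade fossil records and estimator validation.

A simulated clade draws its origination age from U[100, 600] Ma and its
extinction age from U[10, 0.9 * t_origin] Ma. True diversity between those
endpoints follows a random-walk excursion: a Gaussian random-walk bridge
rotated at its minimum (the Vervaat construction), which starts and ends
at one lineage and stays positive in between — a clade waxes from a single
lineage and wanes back to one before dying. The excursion is scaled so its
peak equals a per-dataset standing richness drawn lognormally (median
1,000 species, log-sd 0.7), sized so that with the fossilization rates
below roughly half of all lifespan bins yield no fossils, as in empirical
family-level records. Fossil counts per 1-Myr bin are Poisson draws under
per-bin sampling rates drawn from an exponential distribution (mean
~0.0067 per lineage per Myr, i.e. about one fossil per bin per 150
standing lineages) modulated by a mild linear increase toward the present;
a random fraction of bins (drawn per dataset from U[0.1, 0.5]) gets rate
zero to emulate gaps in the rock record. Accuracy of the inference is
scored with signed relative errors (estimate - truth) / truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mcmc import MCMCConfig, ess, run_mcmc, summarize_trace
from .pbdb_io import BinnedCounts

__all__ = [
    "SimulatedClade",
    "ValidationSummary",
    "brownian_bridge_path",
    "simulate_trajectory",
    "simulate_fossil_counts",
    "simulate_clade",
    "simulate_batch",
    "relative_error",
    "validate",
]

#: Variance per Myr of the raw random walk shaping the excursion. Because
#: the path is rescaled to its peak richness, the shape is scale-invariant
#: in this value; it only matters through the zero-variance limit
#: (diversity identically 1).
DEFAULT_SIG2_SIM = 0.05

#: Per-dataset peak standing richness: lognormal(log(PEAK_MEDIAN), PEAK_LOG_SD).
#: Sized so the fossilization arithmetic below leaves roughly half of all
#: lifespan bins empty, as in empirical family-level records.
PEAK_MEDIAN = 1000.0
PEAK_LOG_SD = 0.7

DEFAULT_MEAN_RATE = 0.0067
DEFAULT_TREND = 1.0  # linear rate increase: youngest bin ~ (1+TREND)/(1) x oldest, mean-preserving


def brownian_bridge_path(n_steps: int, sig2: float, rng, bin_width: float = 1.0) -> np.ndarray:
    """Brownian bridge of ``n_steps`` increments pinned at 0 at both ends.

    Returns ``n_steps + 1`` values; the midpoint is mean-zero with variance
    ``sig2 * w * n/4``.
    """
    if n_steps < 1:
        return np.zeros(1)
    incr = rng.normal(0.0, np.sqrt(sig2 * bin_width), size=n_steps)
    walk = np.concatenate([[0.0], np.cumsum(incr)])
    t = np.arange(n_steps + 1) / n_steps
    return walk - t * walk[-1]


def excursion_path(n_steps: int, sig2: float, rng, bin_width: float = 1.0) -> np.ndarray:
    """Non-negative random-walk excursion pinned at 0 at both ends.

    Vervaat construction: a Brownian bridge rotated at its minimum, which
    turns the bridge into a path that leaves 0, stays positive and returns
    to 0 — the shape of a clade that waxes from one lineage and wanes back.
    """
    b = brownian_bridge_path(n_steps, sig2, rng, bin_width)
    if len(b) < 3:
        return np.zeros_like(b)
    i = int(np.argmin(b))
    return np.concatenate([b[i:], b[1 : i + 1]]) - b[i]


def simulate_trajectory(
    t_origin: float,
    t_ext: float,
    sig2_sim: float = DEFAULT_SIG2_SIM,
    seed: int | np.random.Generator = 0,
    bin_width: float = 1.0,
    peak_diversity: float = PEAK_MEDIAN,
) -> np.ndarray:
    """True diversity per lifespan bin, youngest bin first.

    A random-walk excursion (variance ``sig2_sim`` per Myr) scaled so its
    maximum equals ``peak_diversity``, with both the origin bin and the
    final pre-extinction bin at exactly one lineage and every value >= 1.
    Covers bins ``floor(t_ext) .. floor(t_origin)`` inclusive. With
    ``sig2_sim = 0`` the path is identically one lineage.
    """
    if t_ext >= t_origin:
        raise ValueError("t_ext must be younger than t_origin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tb = int(t_ext // bin_width)
    ob = int(t_origin // bin_width)
    e = excursion_path(ob - tb, sig2_sim, rng, bin_width)
    peak = float(e.max())
    if peak <= 0.0:
        return np.ones_like(e)
    return 1.0 + (max(peak_diversity, 1.0) - 1.0) * e / peak


def _bin_rates(
    n_bins: int,
    mean_rate: float,
    zero_fraction: float,
    trend: float,
    rng,
) -> np.ndarray:
    """Per-bin sampling rates, youngest bin first."""
    r = rng.exponential(mean_rate, size=n_bins)
    if trend > 0 and n_bins > 1:
        u = np.linspace(1.0, 0.0, n_bins)  # elapsed-time fraction; youngest first
        f = (1.0 + trend * u) / (1.0 + trend * 0.5)
        r = r * f
    n_zero = int(round(zero_fraction * n_bins))
    if n_zero > 0:
        r[rng.choice(n_bins, size=n_zero, replace=False)] = 0.0
    return r


def simulate_fossil_counts(
    trajectory: np.ndarray,
    mean_rate: float = DEFAULT_MEAN_RATE,
    zero_fraction: float = 0.3,
    seed: int | np.random.Generator = 0,
    trend: float = DEFAULT_TREND,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson fossil counts for a true-diversity trajectory.

    Returns ``(counts, rates)`` over the lifespan bins (youngest first).
    Counts are Poisson with mean ``N_i * (1 - exp(-r_i))``; a bin whose
    draw exceeds ``floor(N_i)`` is redrawn so that sampled diversity never
    exceeds true diversity. All-zero outcomes are the caller's concern.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # cap richness far above anything biological to keep Poisson draws finite
    n = np.minimum(np.asarray(trajectory, dtype=float), 1e12)
    r = _bin_rates(len(n), mean_rate, zero_fraction, trend, rng)
    lam = n * -np.expm1(-r)
    counts = rng.poisson(lam)
    cap = np.floor(n).astype(np.int64)
    bad = np.flatnonzero(counts > cap)
    for i in bad:
        while counts[i] > cap[i]:
            counts[i] = rng.poisson(lam[i])
    return counts.astype(np.int64), r


@dataclass
class SimulatedClade:
    """Ground truth and generated record for one validation dataset."""

    true_t_origin: float
    true_t_ext: float
    trajectory: np.ndarray  # true diversity, youngest lifespan bin first
    rates: np.ndarray
    counts: BinnedCounts
    terminal_bin: int
    zero_fraction_config: float
    n_redraws: int = 0

    @property
    def zero_bin_fraction(self) -> float:
        """Fraction of lifespan bins with zero sampled species."""
        tb = self.terminal_bin
        ob = tb + len(self.trajectory) - 1
        span = self.counts.counts[tb : ob + 1]
        n_span = ob - tb + 1
        n_zero = n_span - np.count_nonzero(span)
        return float(n_zero / n_span)


def simulate_clade(
    rng: np.random.Generator,
    sig2_sim: float = DEFAULT_SIG2_SIM,
    mean_rate: float = DEFAULT_MEAN_RATE,
    trend: float = DEFAULT_TREND,
    zero_fraction_range: tuple[float, float] = (0.1, 0.5),
    bin_width: float = 1.0,
    peak_median: float = PEAK_MEDIAN,
    peak_log_sd: float = PEAK_LOG_SD,
) -> SimulatedClade:
    """Draw one extinct clade; redraw until its record has >= 1 fossil."""
    n_redraws = 0
    while True:
        t_origin = float(rng.uniform(100.0, 600.0))
        t_ext = float(rng.uniform(10.0, 0.9 * t_origin))
        zf = float(rng.uniform(*zero_fraction_range))
        peak = float(np.exp(rng.normal(np.log(peak_median), peak_log_sd)))
        traj = simulate_trajectory(t_origin, t_ext, sig2_sim, rng, bin_width, peak)
        tb = int(t_ext // bin_width)
        lifespan_counts, rates = simulate_fossil_counts(traj, mean_rate, zf, rng, trend)
        if lifespan_counts.any():
            break
        n_redraws += 1
    full = np.zeros(tb + len(traj), dtype=np.int64)
    full[tb:] = lifespan_counts
    counts = BinnedCounts(
        family=f"sim_{t_origin:.1f}_{t_ext:.1f}",
        counts=full,
        n_extant=0,
        bin_width=bin_width,
    )
    return SimulatedClade(
        true_t_origin=t_origin,
        true_t_ext=t_ext,
        trajectory=traj,
        rates=rates,
        counts=counts,
        terminal_bin=tb,
        zero_fraction_config=zf,
        n_redraws=n_redraws,
    )


def simulate_batch(n: int = 200, seed: int = 0, **kwargs) -> list[SimulatedClade]:
    """Independent validation clades; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [simulate_clade(rng, **kwargs) for _ in range(n)]


def relative_error(estimate: float, truth: float) -> float:
    """Signed relative error (estimate - truth) / truth."""
    if truth == 0:
        raise ValueError("truth must be nonzero")
    return (estimate - truth) / truth


@dataclass
class ValidationSummary:
    """Accuracy of the estimator over a simulated batch.

    Relative errors use the posterior median; coverage counts the datasets
    whose true value falls inside the 95% HPD interval. Non-converged
    chains (min ESS below the rule) are excluded from the statistics and
    counted in ``n_nonconverged``.
    """

    root_errors: np.ndarray
    ext_errors: np.ndarray
    root_abs_mean: float
    root_abs_sd: float
    ext_abs_mean: float
    ext_abs_sd: float
    root_mean_signed: float
    ext_mean_signed: float
    root_interval_widths: np.ndarray
    ext_interval_widths: np.ndarray
    root_coverage: float
    ext_coverage: float
    zero_bin_fractions: np.ndarray
    q_estimates: np.ndarray
    a_estimates: np.ndarray
    n_fossils: np.ndarray
    n_nonconverged: int
    estimates: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "root_abs_mean": self.root_abs_mean,
            "root_abs_sd": self.root_abs_sd,
            "ext_abs_mean": self.ext_abs_mean,
            "ext_abs_sd": self.ext_abs_sd,
            "root_mean_signed": self.root_mean_signed,
            "ext_mean_signed": self.ext_mean_signed,
            "root_coverage": self.root_coverage,
            "ext_coverage": self.ext_coverage,
            "mean_zero_bin_pct": 100.0 * float(np.mean(self.zero_bin_fractions)),
            "n_nonconverged": self.n_nonconverged,
        }


def validate(
    batch: list[SimulatedClade],
    config: MCMCConfig,
    ess_rule: float = 100.0,
) -> ValidationSummary:
    """Run the sampler on every simulated clade and score the estimates."""
    if not batch:
        raise ValueError("empty batch")
    rows = []
    estimates = []
    n_bad = 0
    for i, clade in enumerate(batch):
        cfg = MCMCConfig(**{**config.__dict__, "seed": config.seed + 1000 * i})
        trace = run_mcmc(clade.counts, cfg)
        est = summarize_trace(trace, clade.counts, ess_target=ess_rule)
        estimates.append(est)
        if not est.converged:
            n_bad += 1
            continue
        rows.append(
            (
                relative_error(est.root_est, clade.true_t_origin),
                relative_error(est.ext_est, clade.true_t_ext),
                est.root_upper - est.root_lower,
                est.ext_upper - est.ext_lower,
                est.root_lower <= clade.true_t_origin <= est.root_upper,
                est.ext_lower <= clade.true_t_ext <= est.ext_upper,
                clade.zero_bin_fraction,
                est.q_est,
                est.a_est,
                clade.counts.n_fossils,
            )
        )
    if not rows:
        raise RuntimeError("no converged datasets to summarize")
    arr = np.asarray(rows, dtype=float)
    root_err, ext_err = arr[:, 0], arr[:, 1]
    return ValidationSummary(
        root_errors=root_err,
        ext_errors=ext_err,
        root_abs_mean=float(np.mean(np.abs(root_err))),
        root_abs_sd=float(np.std(np.abs(root_err))),
        ext_abs_mean=float(np.mean(np.abs(ext_err))),
        ext_abs_sd=float(np.std(np.abs(ext_err))),
        root_mean_signed=float(np.mean(root_err)),
        ext_mean_signed=float(np.mean(ext_err)),
        root_interval_widths=arr[:, 2],
        ext_interval_widths=arr[:, 3],
        root_coverage=float(np.mean(arr[:, 4])),
        ext_coverage=float(np.mean(arr[:, 5])),
        zero_bin_fractions=arr[:, 6],
        q_estimates=arr[:, 7],
        a_estimates=arr[:, 8],
        n_fossils=arr[:, 9],
        n_nonconverged=n_bad,
        estimates=estimates,
    )
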