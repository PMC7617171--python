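import math

import numpy as np
import pytest
from scipy.stats import norm, poisson

from fossilbridge.bbb_core import (
    BBBParams,
    BBBState,
    PriorConfig,
    Trajectory,
    log_bridge_density,
    log_posterior,
    log_prior,
    log_sampling_lik,
    sampling_rate_at,
)
from fossilbridge.pbdb_io import BinnedCounts


def _params(**kw):
    base = dict(t_origin=8.5, t_ext=None, sig2=0.5, q0=0.2, a=1.0)
    base.update(kw)
    return BBBParams(**base)


class TestSamplingRate:
    def test_rate_at_origin_is_q0(self):
        p = _params(q0=0.37)
        assert sampling_rate_at(p.t_origin, p) == pytest.approx(0.37)

    def test_no_trend_is_flat(self):
        p = _params(a=0.0, q0=0.2)
        for t in [0.0, 3.3, 8.5]:
            assert sampling_rate_at(t, p) == pytest.approx(0.2)

    def test_exponential_increase_value(self):
        # one decade of increase over the full lifespan
        p = _params(t_origin=100.0, q0=0.1, a=math.log(10.0))
        assert sampling_rate_at(0.0, p) == pytest.approx(1.0)

    def test_monotone_toward_present(self):
        p = _params(a=2.0)
        ts = np.linspace(0.0, p.t_origin, 30)
        qs = [sampling_rate_at(t, p) for t in ts]
        assert all(a >= b for a, b in zip(qs, qs[1:]))  # ts increase toward past

    def test_outside_lifespan_errors(self):
        p = _params(t_ext=2.0, t_origin=8.5)
        with pytest.raises(ValueError):
            sampling_rate_at(1.0, p)
        with pytest.raises(ValueError):
            sampling_rate_at(9.0, p)


class TestBridgeDensity:
    def test_one_step_bridge(self):
        traj = Trajectory(x=np.array([0.0, 0.0]), terminal_bin=0)
        assert log_bridge_density(traj, sig2=0.7) == pytest.approx(
            norm.logpdf(0.0, scale=math.sqrt(0.7))
        )

    def test_constant_path_symmetry(self):
        traj = Trajectory(x=np.zeros(6), terminal_bin=0)
        assert log_bridge_density(traj, sig2=1.3) == pytest.approx(
            5 * norm.logpdf(0.0, scale=math.sqrt(1.3))
        )

    def test_term_by_term_oracle(self):
        x = np.array([0.3, 1.1, 0.2, 0.0])
        traj = Trajectory(x=x, terminal_bin=2)
        expected = sum(
            norm.logpdf(x[i + 1] - x[i], scale=math.sqrt(0.5)) for i in range(3)
        )
        assert log_bridge_density(traj, sig2=0.5) == pytest.approx(expected)

    def test_requires_positive_variance(self):
        with pytest.raises(ValueError):
            log_bridge_density(Trajectory(x=np.zeros(3), terminal_bin=0), sig2=0.0)


class TestSamplingLik:
    def test_zero_bins_vanish_as_rate_goes_to_zero(self, extinct_counts):
        """With q -> 0 every empty bin's contribution -lambda tends to 0,
        leaving only the occupied bins' Poisson terms."""
        tb = 2
        x = np.zeros(7)  # bins 2..8
        x[1] = math.log(2.0)  # bin 3 holds 2 species
        params = _params(t_origin=8.9, t_ext=2.5, q0=1e-9, a=0.0)
        traj = Trajectory(x=x, terminal_bin=tb)
        got = log_sampling_lik(traj, extinct_counts, params)
        p = -math.expm1(-1e-9)
        occupied = (
            poisson.logpmf(2, 2.0 * p) + poisson.logpmf(1, p) + poisson.logpmf(1, p)
        )
        assert got == pytest.approx(occupied, rel=1e-9)

    def test_single_bin_poisson_value(self):
        counts = BinnedCounts(family="X", counts=np.array([1, 0]), n_extant=0)
        q = 0.105
        params = BBBParams(t_origin=1.9, t_ext=None, sig2=1.0, q0=q, a=0.0)
        x = np.array([math.log(10.0), 0.0])
        traj = Trajectory(x=x, terminal_bin=0)
        p = 1.0 - math.exp(-q)  # ~0.0997
        expected = poisson.logpmf(1, 10.0 * p) + poisson.logpmf(0, 1.0 * p)
        assert log_sampling_lik(traj, counts, params) == pytest.approx(expected)

    def test_support_violation_is_minus_inf(self):
        # latent diversity 2 under a sampled count of 3
        counts3 = BinnedCounts(family="X", counts=np.array([0, 3, 0]), n_extant=1)
        params3 = BBBParams(t_origin=2.9, sig2=1.0, q0=0.2, a=0.0)
        traj3 = Trajectory(x=np.array([0.0, math.log(2.0), 0.0]), terminal_bin=0)
        assert log_sampling_lik(traj3, counts3, params3) == -np.inf

    def test_extinct_clade_alive_below_one_lineage_is_minus_inf(self):
        counts = BinnedCounts(family="X", counts=np.array([0, 0, 1, 0]), n_extant=0)
        params = BBBParams(t_origin=3.5, t_ext=0.5, sig2=1.0, q0=0.2, a=0.0)
        traj = Trajectory(x=np.array([0.0, -0.4, 0.2, 0.0]), terminal_bin=0)
        assert log_sampling_lik(traj, counts, params) == -np.inf


class TestPrior:
    def test_origin_beyond_cap(self, extinct_counts):
        p = _params(t_origin=700.0, t_ext=1.0)
        assert log_prior(p, extinct_counts) == -np.inf

    def test_extinction_after_youngest_fossil(self, extinct_counts):
        # youngest fossil at 3 Ma; extinction must be younger
        p = _params(t_origin=20.0, t_ext=4.0)
        assert log_prior(p, extinct_counts) == -np.inf
        assert np.isfinite(log_prior(_params(t_origin=20.0, t_ext=1.5), extinct_counts))

    def test_componentwise_value(self, extinct_counts):
        cfg = PriorConfig()
        p = _params(t_origin=100.0, t_ext=1.0, q0=1.0, a=10.0, sig2=1.0)
        expected = (
            -math.log(cfg.origin_cap - extinct_counts.oldest_fossil)
            - math.log(extinct_counts.youngest_fossil)
            + (-math.log(1.0) - 1.0)
            + (-math.log(10.0) - 1.0)
            + (-math.log(1.0) - 1.0)
        )
        assert log_prior(p, extinct_counts, cfg) == pytest.approx(expected)


class TestPosterior:
    def _state(self, extinct_counts, **kw):
        params = _params(t_origin=7.5, t_ext=1.5, **kw)
        # bins 1..7: the origin bin implied by t_origin = 7.5
        x = np.log(np.maximum(extinct_counts.counts[1:8].astype(float), 1.0))
        x[0] = 0.0
        x[-1] = 0.0
        traj = Trajectory(x=x, terminal_bin=1)
        return BBBState(params=params, traj=traj)

    def test_componentwise_sum(self, extinct_counts):
        st = self._state(extinct_counts)
        total = log_posterior(st, extinct_counts)
        parts = (
            log_prior(st.params, extinct_counts)
            + log_bridge_density(st.traj, st.params.sig2)
            + log_sampling_lik(st.traj, extinct_counts, st.params)
        )
        assert total == pytest.approx(parts)

    def test_sig2_only_moves_bridge_term(self, extinct_counts):
        st1 = self._state(extinct_counts, sig2=0.5)
        st2 = self._state(extinct_counts, sig2=1.0)
        diff = log_posterior(st2, extinct_counts) - log_posterior(st1, extinct_counts)
        bridge_diff = log_bridge_density(st2.traj, 1.0) - log_bridge_density(st1.traj, 0.5)
        prior_diff = log_prior(st2.params, extinct_counts) - log_prior(st1.params, extinct_counts)
        assert diff == pytest.approx(bridge_diff + prior_diff)

    def test_zero_padding_older_than_origin_is_ignored(self, extinct_counts):
        st = self._state(extinct_counts)
        padded = BinnedCounts(
            family=extinct_counts.family,
            counts=np.concatenate([extinct_counts.counts, np.zeros(30, dtype=int)]),
            n_extant=0,
            oldest_fossil=extinct_counts.oldest_fossil,
            youngest_fossil=extinct_counts.youngest_fossil,
        )
        assert log_posterior(st, padded) == pytest.approx(log_posterior(st, extinct_counts))

    def test_mismatched_span_is_minus_inf(self, extinct_counts):
        st = self._state(extinct_counts)
        st.params = st.params.copy(t_origin=12.0)  # origin bin no longer matches traj
        assert log_posterior(st, extinct_counts) == -np.inf
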