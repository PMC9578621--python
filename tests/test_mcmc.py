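"""Hierarchical likelihood, priors, sampler and chain diagnostics."""

import math

import numpy as np
import pytest

import ferticast as fc
from ferticast.config import MCMCConfig
from ferticast.exceptions import ModelError
from ferticast.mcmc import (
    ModelState,
    Phase2Sampler,
    RegionState,
    _ess,
    _rhat,
    summarize_posterior,
)

from .conftest import make_series


def _norm_logpdf(x, mu, sd):
    return -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((x - mu) / sd) ** 2


class TestPhase2Loglik:
    DIST = fc.DistortionParams(m_tau=0.1, s_tau=0.2, sigma0=0.15, S=4.5, a=0.02, b=0.02, c1975=1.3)

    def _series_from_theta(self, theta, f_start, n, start_year=1980):
        vals = [f_start]
        for _ in range(n):
            vals.append(vals[-1] - float(fc.decrement(theta, vals[-1])))
        return make_series(vals, start_year=start_year)

    def test_zero_residual_step(self, example_theta):
        s = self._series_from_theta(example_theta, 5.0, 2)
        pa = fc.PhaseAssignment(tau=fc.BEFORE_OBSERVATION, lam=fc.NOT_REACHED,
                                phase_per_period=(fc.Phase.II,) * 3)
        ll = fc.phase2_loglik(s, pa, example_theta, self.DIST)
        expected = sum(
            _norm_logpdf(0.0, 0.0, fc.sigma_eps(float(s.values[t]), t, self.DIST, s.grid))
            for t in range(2)
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_unit_standardized_residual(self, example_theta):
        f0 = 5.0
        sd = fc.sigma_eps(f0, 0, self.DIST, fc.PeriodGrid(1980, 2))
        f1 = f0 - float(fc.decrement(example_theta, f0)) + sd
        s = make_series([f0, f1], start_year=1980)
        pa = fc.PhaseAssignment(tau=fc.BEFORE_OBSERVATION, lam=fc.NOT_REACHED,
                                phase_per_period=(fc.Phase.II,) * 2)
        ll = fc.phase2_loglik(s, pa, example_theta, self.DIST)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * sd**2) - 0.5, rel=1e-12)

    def test_onset_step_uses_start_distortion(self, example_theta):
        s = make_series([5.5, 6.0, 5.2, 4.3], start_year=1980)
        pa = fc.PhaseAssignment(tau=1, lam=fc.NOT_REACHED,
                                phase_per_period=(fc.Phase.I, fc.Phase.II, fc.Phase.II, fc.Phase.II))
        ll = fc.phase2_loglik(s, pa, example_theta, self.DIST)
        v = s.values
        eps1 = v[2] - v[1] + float(fc.decrement(example_theta, v[1]))
        eps2 = v[3] - v[2] + float(fc.decrement(example_theta, v[2]))
        expected = _norm_logpdf(eps1, self.DIST.m_tau, self.DIST.s_tau) + _norm_logpdf(
            eps2, 0.0, fc.sigma_eps(float(v[2]), 2, self.DIST, s.grid)
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_three_step_brute_force_regression(self, example_theta):
        # frozen from an independent step-by-step evaluation of the density
        s = make_series([6.0, 5.3, 4.5, 3.9], start_year=1960)
        pa = fc.PhaseAssignment(tau=0, lam=fc.NOT_REACHED,
                                phase_per_period=(fc.Phase.II,) * 4)
        ll = fc.phase2_loglik(s, pa, example_theta, self.DIST)
        v = s.values
        expected = 0.0
        for t in range(3):
            d = float(fc.decrement(example_theta, float(v[t])))
            eps = float(v[t + 1] - v[t]) + d
            if t == 0:
                expected += _norm_logpdf(eps, 0.1, 0.2)
            else:
                sd = self.DIST.c1975 * (0.15 + (float(v[t]) - 4.5) * (-0.02 if v[t] >= 4.5 else 0.02))
                expected += _norm_logpdf(eps, 0.0, sd)
        assert ll == pytest.approx(expected, rel=1e-12)
        assert ll == pytest.approx(-7.657864653342847, rel=1e-9)

    def test_no_transition_steps_is_error(self, example_theta):
        s = make_series([1.8, 1.7, 1.75, 1.9])
        pa = fc.PhaseAssignment(tau=fc.BEFORE_OBSERVATION, lam=0,
                                phase_per_period=(fc.Phase.III,) * 4)
        with pytest.raises(ModelError):
            fc.phase2_loglik(s, pa, example_theta, self.DIST)


class TestLogPrior:
    CFG = MCMCConfig(chains=2, iterations=10, burn_in=5, thin=1)

    def _state(self, U=7.0, **kw):
        region = RegionState(d_star=kw.get("d_star", 0.0), delta4_star=0.0,
                             gamma=(0.0, 0.0, 0.0), U=U, U_sampled=True)
        hyper = fc.HierarchyParams(chi=kw.get("chi", 0.0), psi=kw.get("psi", 1.0),
                                   Delta4_mean=0.0, delta4_sd=1.0,
                                   alpha=(0.0, 0.0, 0.0), delta_sd=(1.0, 1.0, 1.0))
        return ModelState(regions={"A": region}, hyper=hyper, dist=fc.DistortionParams())

    def test_onset_level_above_cap_is_minus_inf(self):
        assert fc.log_prior(self._state(U=9.0), self.CFG) == -math.inf

    def test_region_terms_at_mode_standard_normal(self):
        lp = fc.log_prior(self._state(), self.CFG, U_bounds={"A": (5.5, 8.8)})
        lp0 = fc.log_prior(self._state(d_star=1.0), self.CFG, U_bounds={"A": (5.5, 8.8)})
        # moving d* one unit off the hierarchy mean costs exactly 1/2
        assert lp - lp0 == pytest.approx(0.5, rel=1e-12)

    def test_hyperparameter_outside_support_is_minus_inf(self):
        assert fc.log_prior(self._state(chi=7.0), self.CFG) == -math.inf
        assert fc.log_prior(self._state(psi=9.0), self.CFG) == -math.inf


class TestSampler:
    def test_seeded_runs_bit_identical(self, small_panel, small_phases, tiny_mcmc_config):
        panel, _ = small_panel
        a = fc.run_mcmc(panel, small_phases, tiny_mcmc_config)
        b = fc.run_mcmc(panel, small_phases, tiny_mcmc_config)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_posterior, b.log_posterior)
        assert a.param_names == b.param_names

    def test_draw_count_contract(self, small_sample, tiny_mcmc_config):
        cfg = tiny_mcmc_config
        per_chain = (cfg.iterations - cfg.burn_in + cfg.thin - 1) // cfg.thin
        assert small_sample.n_draws == cfg.chains * per_chain

    def test_no_retained_draw_violates_supports(self, small_sample):
        s = small_sample
        pr = s.config.priors
        for name in s.param_names:
            col = s.column(name)
            assert np.all(np.isfinite(col))
            if name.startswith("U["):
                rid = name[2:-1]
                lo, hi = s.U_bounds[rid]
                assert np.all((col > lo) & (col < hi))
        for nm, bounds in [("psi", pr.psi), ("s_tau", pr.s_tau), ("sigma0", pr.sigma0),
                           ("S", pr.S), ("c1975", pr.c1975)]:
            col = s.column(nm)
            assert np.all((col > bounds[0]) & (col < bounds[1]))

    def test_logposterior_reproducible_from_states(self, small_panel, small_phases, small_sample):
        panel, _ = small_panel
        s = small_sample
        for i in (0, s.n_draws // 2, s.n_draws - 1):
            st = s.state_at(i)
            lp = fc.log_prior(st, s.config, U_bounds=s.U_bounds)
            for ser in panel.series:
                lp += fc.phase2_loglik(
                    ser, small_phases[ser.region_id],
                    st.regions[ser.region_id].to_decline_params(), st.dist,
                )
            assert lp == pytest.approx(s.log_posterior[i], rel=1e-9)
            assert math.isfinite(lp)

    def test_all_phase3_panel_rejected(self):
        s = make_series([1.8, 1.7, 1.75, 1.9])
        panel = fc.TFRPanel([s])
        pa = fc.PhaseAssignment(tau=fc.BEFORE_OBSERVATION, lam=0,
                                phase_per_period=(fc.Phase.III,) * 4)
        with pytest.raises(ModelError):
            fc.run_mcmc(panel, {"X": pa}, MCMCConfig(chains=1, iterations=10, burn_in=5, thin=1))

    def test_collapsed_posterior_matches_grid(self, small_panel, small_phases):
        """With one free coordinate the sampler must reproduce the exact
        conditional posterior (checked against dense grid integration)."""
        panel, _ = small_panel
        cfg = MCMCConfig(chains=2, iterations=3_000, burn_in=500, thin=1, seed=21)
        sampler = Phase2Sampler(panel, small_phases, cfg)
        target = f"d_star[{sampler.region_ids[0]}]"
        fixed = {
            p.name: p.init for p in sampler.params if p.name != target
        }
        fixed["psi"] = 0.4
        cfg = MCMCConfig(chains=2, iterations=3_000, burn_in=500, thin=1, seed=21,
                         fixed_params=fixed)
        sample = fc.run_mcmc(panel, small_phases, cfg)
        draws = sample.column(target)

        sampler = Phase2Sampler(panel, small_phases, cfg)
        base = sampler._init_state(np.random.default_rng(0))
        ti = sampler.param_names.index(target)
        grid = np.linspace(draws.min() - 0.5, draws.max() + 0.5, 1500)
        logp = np.empty_like(grid)
        for j, g in enumerate(grid):
            base[ti] = g
            logp[j] = sampler.log_posterior(base)
        dens = np.exp(logp - logp.max())
        dens /= np.trapezoid(dens, grid)
        edges = np.linspace(grid[0], grid[-1], 31)
        p_mcmc = np.histogram(draws, bins=edges)[0] / len(draws)
        cdf = np.concatenate([[0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        p_grid = np.diff(np.interp(edges, grid, cdf))
        tv = 0.5 * np.abs(p_mcmc - p_grid).sum()
        assert tv < 0.08  # full-scale check lives in the acceptance suite


class TestSummaries:
    def _sample_from(self, draws_by_chain):
        draws = np.concatenate(draws_by_chain)[:, None]
        chain = np.concatenate([np.full(len(c), i) for i, c in enumerate(draws_by_chain)])
        from ferticast.mcmc import PosteriorSample

        return PosteriorSample(
            draws=draws, param_names=["x"], chain_id=chain,
            iteration=np.arange(len(draws)), log_posterior=np.zeros(len(draws)),
            region_ids=[], fixed_U={}, U_bounds={}, acceptance={},
            config=MCMCConfig(chains=2, iterations=10, burn_in=5, thin=1), warnings_=[],
        )

    def test_constant_chain(self):
        s = self._sample_from([np.full(50, 3.0), np.full(50, 3.0)])
        row = summarize_posterior(s).loc["x"]
        assert row["Mean"] == 3.0 and row["SD"] == 0.0
        assert row["Naive SE"] == 0.0 and row["Time-series SE"] == 0.0
        assert all(row[q] == 3.0 for q in ["2.5%", "25%", "50%", "75%", "97.5%"])

    def test_iid_normal_ses_agree(self):
        rng = np.random.default_rng(1)
        s = self._sample_from([rng.standard_normal(5000), rng.standard_normal(5000)])
        row = summarize_posterior(s).loc["x"]
        assert row["Naive SE"] == pytest.approx(0.01, rel=0.1)
        assert row["Time-series SE"] == pytest.approx(row["Naive SE"], rel=0.2)

    def test_quantile_columns_ordered(self, small_sample):
        df = summarize_posterior(small_sample)
        q = df[["2.5%", "25%", "50%", "75%", "97.5%"]].to_numpy()
        assert np.all(np.diff(q, axis=1) >= 0)

    def test_summary_has_table_column_sets(self, small_sample):
        df = summarize_posterior(small_sample)
        assert list(df.columns) == [
            "Mean", "SD", "Naive SE", "Time-series SE",
            "2.5%", "25%", "50%", "75%", "97.5%",
        ]


class TestDiagnostics:
    def test_identical_stationary_chains_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        assert _rhat([x, x]) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 5.0
        assert _rhat([a, b]) > 2.0

    def test_white_noise_ess_in_range(self):
        rng = np.random.default_rng(4)
        chains = [rng.standard_normal(1000), rng.standard_normal(1000)]
        assert 1000 <= _ess(chains) <= 3000

    def test_single_chain_rejected(self, small_panel, small_phases):
        panel, _ = small_panel
        cfg = MCMCConfig(chains=1, iterations=100, burn_in=50, thin=1, seed=2)
        sample = fc.run_mcmc(panel, small_phases, cfg)
        with pytest.raises(ModelError):
            fc.convergence_diagnostics(sample)

    def test_matches_arviz_on_random_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(6)
        # AR(1)-correlated chains: a case where both Rhat and ESS are non-trivial
        chains = []
        for _ in range(4):
            e = rng.standard_normal(2000)
            x = np.empty(2000)
            x[0] = e[0]
            for i in range(1, 2000):
                x[i] = 0.6 * x[i - 1] + e[i]
            chains.append(x)
        arr = np.array(chains)
        assert _rhat(chains) == pytest.approx(float(az.rhat(arr)), abs=0.02)
        assert _ess(chains) == pytest.approx(float(az.ess(arr)), rel=0.25)

    def test_warns_on_bad_rhat(self, small_panel, small_phases):
        panel, _ = small_panel
        # deliberately non-converged: tiny run from jittered inits
        cfg = MCMCConfig(chains=2, iterations=40, burn_in=10, thin=1, seed=8)
        sample = fc.run_mcmc(panel, small_phases, cfg)
        with pytest.warns(UserWarning, match="Rhat"):
            fc.convergence_diagnostics(sample)
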