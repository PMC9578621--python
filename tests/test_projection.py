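"""Trajectory simulation, quantile summaries and fertility variants."""

import numpy as np
import pytest

import ferticast as fc
from ferticast.config import ProjectionConfig
from ferticast.exceptions import ModelError
from ferticast.io import QUANTILE_PROBS, make_quantile_table
from ferticast.mcmc import PosteriorSample

from .conftest import make_series


def phase3_assignment(n):
    return fc.PhaseAssignment(
        tau=fc.BEFORE_OBSERVATION, lam=0, phase_per_period=(fc.Phase.III,) * n
    )


def phase2_assignment(n):
    return fc.PhaseAssignment(
        tau=fc.BEFORE_OBSERVATION, lam=fc.NOT_REACHED, phase_per_period=(fc.Phase.II,) * n
    )


@pytest.fixture(scope="module")
def truth_posterior():
    """Degenerate single-draw posterior at a known parameter state."""
    panel, truth = fc.generate_panel(fc.SyntheticSpec(n_regions=2, seed=23))
    return panel, truth, PosteriorSample.from_states([truth.to_model_state()])


class TestSimulateRegion:
    def test_noiseless_phase3_follows_ar1_closed_form(self):
        s = make_series([1.8, 1.7, 1.75, 1.3])
        ar1 = fc.AR1Params(rho=0.9, s=0.0)
        cfg = ProjectionConfig(horizon_end_year=1995, n_trajectories=3, seed=1)
        ts = fc.simulate_region(s, phase3_assignment(4), None, ar1, cfg)
        expected = []
        f = 1.3
        for _ in range(len(ts.grid)):
            f = 2.1 + 0.9 * (f - 2.1)
            expected.append(f)
        for k in range(3):
            np.testing.assert_allclose(ts.trajectories[k], expected, rtol=1e-12)
        assert ts.quantiles.years[0] == 1973

    def test_seeded_rerun_bit_identical(self, truth_posterior):
        panel, _, post = truth_posterior
        s = panel.series[0]
        pa = fc.assign_phases(s)
        ar1 = fc.AR1Params(rho=0.9, s=0.05)
        cfg = ProjectionConfig(n_trajectories=200, seed=7)
        a = fc.simulate_region(s, pa, post, ar1, cfg)
        b = fc.simulate_region(s, pa, post, ar1, cfg)
        np.testing.assert_array_equal(a.trajectories, b.trajectories)
        np.testing.assert_array_equal(a.phase_at, b.phase_at)

    def test_noiseless_phase2_equals_deterministic_recursion(self, truth_posterior):
        panel, truth, _ = truth_posterior
        rid = panel.series[0].region_id
        rt = truth.regions[rid]
        # zero all distortion scales so transition steps are deterministic
        state = truth.to_model_state()
        from ferticast.mcmc import ModelState

        dist0 = fc.DistortionParams(m_tau=0.0, s_tau=1e-9, sigma0=1e-9, S=4.5,
                                    a=0.0, b=0.0, c1975=1.0)
        post = PosteriorSample.from_states(
            [ModelState(regions=state.regions, hyper=state.hyper, dist=dist0)]
        )
        s = panel.series[0]
        cfg = ProjectionConfig(horizon_end_year=2045, n_trajectories=2, seed=3,
                               phase3_rule="never")
        ts = fc.simulate_region(s, phase2_assignment(len(s)), post, fc.AR1Params(rho=0.9, s=0.0), cfg)
        f = float(s.values[-1])
        expected = []
        for _ in range(len(ts.grid)):
            f = max(f - float(fc.decrement(rt.theta, f)), cfg.tfr_floor)
            expected.append(f)
        np.testing.assert_allclose(ts.trajectories[0], expected, atol=1e-7)

    def test_phase_switch_is_permanent_and_gate_triggers(self, truth_posterior):
        panel, _, post = truth_posterior
        s = panel.series[0]
        pa = fc.assign_phases(s)
        cfg = ProjectionConfig(n_trajectories=300, seed=9)
        ts = fc.simulate_region(s, pa, post, fc.AR1Params(rho=0.9, s=0.05), cfg)
        for row in ts.phase_at:
            labels = list(row)
            if "III" in labels:
                first = labels.index("III")
                assert all(v == "III" for v in labels[first:])

    def test_no_value_below_floor(self, truth_posterior):
        panel, _, post = truth_posterior
        s = panel.series[0]
        cfg = ProjectionConfig(n_trajectories=300, seed=13, tfr_floor=0.5)
        ts = fc.simulate_region(s, fc.assign_phases(s), post, fc.AR1Params(rho=0.9, s=0.3), cfg)
        assert ts.trajectories.min() >= 0.5

    def test_empty_posterior_rejected(self):
        s = make_series([6.5, 5.0, 4.0])
        post = PosteriorSample.from_states([_dummy_state()])
        post.draws = post.draws[:0]
        with pytest.raises(ModelError):
            fc.simulate_region(s, phase2_assignment(3), post, fc.AR1Params(rho=0.5, s=0.1),
                               ProjectionConfig(n_trajectories=2, seed=1))

    def test_horizon_before_last_observation_rejected(self):
        s = make_series([6.5, 5.0, 4.0])
        with pytest.raises(Exception):
            fc.simulate_region(s, phase3_assignment(3), None, fc.AR1Params(rho=0.5, s=0.1),
                               ProjectionConfig(horizon_end_year=1950, n_trajectories=2, seed=1))


def _dummy_state():
    from ferticast.mcmc import ModelState, RegionState

    return ModelState(
        regions={"X": RegionState(0.0, 0.0, (0.0, 0.0, 0.0), 6.0, U_sampled=False)},
        hyper=fc.HierarchyParams(),
        dist=fc.DistortionParams(),
    )


class TestSummaries:
    def test_single_trajectory_degenerate(self):
        qt = make_quantile_table([2023, 2028], np.array([[1.5, 1.6]]))
        assert np.all(qt.quantiles == qt.median[:, None].repeat(9, axis=1))
        assert np.all(qt.sd == 0.0)

    def test_three_point_median(self):
        qt = make_quantile_table([2023], np.array([[1.0], [2.0], [3.0]]))
        assert qt.median[0] == 2.0
        assert qt.mean[0] == 2.0

    def test_normal_quantiles_recovered(self):
        rng = np.random.default_rng(11)
        draws = rng.normal(1.6, 0.2, size=(10_000, 1))
        qt = make_quantile_table([2023], draws)
        assert qt.quantiles[0, 0] == pytest.approx(1.6 - 1.959964 * 0.2, abs=0.01)
        assert qt.quantiles[0, -1] == pytest.approx(1.6 + 1.959964 * 0.2, abs=0.01)

    def test_quantile_monotone_and_nested(self, truth_posterior):
        panel, _, post = truth_posterior
        s = panel.series[0]
        cfg = ProjectionConfig(n_trajectories=400, seed=17)
        ts = fc.simulate_region(s, fc.assign_phases(s), post, fc.AR1Params(rho=0.9, s=0.05), cfg)
        q = ts.quantiles.quantiles
        assert np.all(np.diff(q, axis=1) >= -1e-12)
        i = {p: j for j, p in enumerate(QUANTILE_PROBS)}
        assert np.all(q[:, i[0.10]] >= q[:, i[0.025]])  # 80% nests in 95%
        assert np.all(q[:, i[0.90]] <= q[:, i[0.975]])


class TestVariants:
    def _qt(self, med):
        med = np.asarray(med, dtype=float)
        q = np.tile(med[:, None], (1, 9))
        years = 2023 + 5 * np.arange(len(med))
        return make_quantile_table(years, np.tile(med, (1, 1))) if False else \
            fc.QuantileTable(years, med, np.zeros(len(med)), q)

    def test_plus_minus_half_child(self):
        hi, lo = fc.make_variants(self._qt([1.5, 1.6]))
        np.testing.assert_allclose(hi, [2.0, 2.1])
        np.testing.assert_allclose(lo, [1.0, 1.1])

    def test_low_variant_floored(self):
        hi, lo = fc.make_variants(self._qt([0.8]), tfr_floor=0.5)
        assert lo[0] == 0.5 and hi[0] == pytest.approx(1.3)

    def test_parallel_where_unfloored(self, truth_posterior):
        panel, _, post = truth_posterior
        s = panel.series[0]
        cfg = ProjectionConfig(n_trajectories=200, seed=19)
        ts = fc.simulate_region(s, fc.assign_phases(s), post, fc.AR1Params(rho=0.9, s=0.05), cfg)
        med = ts.median
        np.testing.assert_allclose(ts.variant_high - med, 0.5, atol=1e-12)
        unfloored = med - 0.5 > cfg.tfr_floor
        np.testing.assert_allclose((med - ts.variant_low)[unfloored], 0.5, atol=1e-12)


class TestProjectPanel:
    def test_all_regions_projected_with_shared_future_grid(self, truth_posterior):
        panel, _, post = truth_posterior
        assignments = {s.region_id: fc.assign_phases(s) for s in panel.series}
        cfg = ProjectionConfig(n_trajectories=50, seed=3)
        results, report = fc.project_panel(panel, assignments, post,
                                           fc.AR1Params(rho=0.9, s=0.05), cfg)
        assert set(results) == set(panel.region_ids)
        grids = {ts.grid for ts in results.values()}
        assert len(grids) == 1
        g = grids.pop()
        assert g.start_of(len(g) - 1) + 5 >= 2100 > g.start_of(len(g) - 1)
        assert set(report["region_id"]) == set(panel.region_ids)

    def test_results_independent_of_panel_ordering(self, truth_posterior):
        panel, _, post = truth_posterior
        assignments = {s.region_id: fc.assign_phases(s) for s in panel.series}
        cfg = ProjectionConfig(n_trajectories=50, seed=3)
        fwd, _ = fc.project_panel(panel, assignments, post, fc.AR1Params(rho=0.9, s=0.05), cfg)
        rev_panel = fc.TFRPanel(list(reversed(panel.series)))
        rev, _ = fc.project_panel(rev_panel, assignments, post, fc.AR1Params(rho=0.9, s=0.05), cfg)
        for rid in panel.region_ids:
            np.testing.assert_array_equal(fwd[rid].trajectories, rev[rid].trajectories)
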