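"""Forward simulation of TFR trajectories and their quantile summaries.

Each trajectory draws one posterior state (parameter uncertainty) and then
iterates 5-year steps (process noise): transition dynamics
f ← f − d(θ, f) + N(0, σ(f)) while the region is in Phase II, switching
permanently to the mean-reverting AR(1) once the post-transition pattern
is met on the simulated path (two consecutive increases with all three
values below 2 children), or immediately when the decrement gate closes
(f ≤ 1).  Regions already post-transition at the end of observation start
directly with AR(1) steps.

The point projection is the median trajectory; fan charts use the
80%/95% prediction bands, and the conventional high/low variants are the
median ± 0.5 children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ar1 import AR1Params
from .config import ProjectionConfig
from .decline import decrement, sigma_eps
from .exceptions import ModelError, ValidationError
from .io import QUANTILE_PROBS, QuantileTable, make_quantile_table
from .mcmc import PosteriorSample
from .periods import PeriodGrid, TFRPanel, TFRSeries
from .phases import LAMBDA_CEILING, Phase, PhaseAssignment

#: TFR level at and below which Phase II drift vanishes (hard-switch level).
GATE_LEVEL = 1.0


@dataclass
class TrajectorySet:
    """Simulated future TFR paths for one region."""

    region_id: str
    grid: PeriodGrid                  # future periods
    trajectories: np.ndarray          # (n_traj, n_future)
    phase_at: np.ndarray              # (n_traj, n_future) of "II"/"III"
    quantiles: QuantileTable
    variant_high: np.ndarray
    variant_low: np.ndarray

    @property
    def median(self) -> np.ndarray:
        return self.quantiles.median


def _future_years(obs_grid: PeriodGrid, horizon_end_year: int) -> PeriodGrid:
    return obs_grid.extended(horizon_end_year)


def make_variants(qt: QuantileTable, tfr_floor: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """High/low fertility variants: median ± 0.5 children, low floored."""
    med = qt.median
    return med + 0.5, np.maximum(med - 0.5, tfr_floor)


def summarize_trajectories(
    trajectories: np.ndarray,
    years,
    probs=QUANTILE_PROBS,
) -> QuantileTable:
    """Mean, sd and empirical quantiles per future period."""
    if np.asarray(trajectories).shape[0] < 1:
        raise ModelError("need at least one trajectory")
    if tuple(probs) != QUANTILE_PROBS:
        raise ValidationError("quantile tables use the canonical nine probabilities")
    return make_quantile_table(years, trajectories)


def simulate_region(
    series: TFRSeries,
    phases: PhaseAssignment,
    posterior: PosteriorSample,
    ar1: AR1Params,
    config: ProjectionConfig,
    seed_offset: int = 0,
) -> TrajectorySet:
    """Simulate ``config.n_trajectories`` future paths for one region.

    One posterior draw (θ_c and distortion parameters) is sampled with
    replacement per trajectory and held fixed along the path, so fan
    charts propagate both parameter uncertainty and process noise.
    Deterministic given ``config.seed`` (per-region streams are separated
    by ``seed_offset``).
    """
    if posterior is not None and posterior.n_draws == 0:
        raise ModelError("posterior sample is empty")
    future = _future_years(series.grid, config.horizon_end_year)
    n_fut = len(future)
    n_traj = config.n_trajectories
    rng = np.random.default_rng([int(config.seed), int(seed_offset)])

    # phase at the end of observation, and the sliding window for the
    # online post-transition pattern (last two observed values)
    starts_phase3 = phases.phase_per_period[-1] == Phase.III
    v = series.values
    tail2 = (float(v[-2]) if len(v) >= 2 else float("inf"), float(v[-1]))

    # pre-draw posterior states; rebuilding per trajectory is the dominant
    # cost, so cache distinct draws
    draw_idx = rng.integers(0, posterior.n_draws, size=n_traj) if posterior is not None else None
    cache: dict[int, tuple] = {}

    traj = np.empty((n_traj, n_fut))
    phase_at = np.empty((n_traj, n_fut), dtype="U3")
    floor = config.tfr_floor
    for k in range(n_traj):
        in_phase3 = bool(starts_phase3)
        theta = dist = None
        if not in_phase3:
            di = int(draw_idx[k])
            if di not in cache:
                st = posterior.state_at(di)
                rs = st.regions.get(series.region_id)
                if rs is None:
                    raise ModelError(
                        f"region {series.region_id!r} absent from the posterior sample"
                    )
                cache[di] = (rs.to_decline_params(), st.dist)
            theta, dist = cache[di]
        prev2, prev1 = tail2
        f = float(v[-1])
        for t in range(n_fut):
            if not in_phase3 and config.phase3_rule == "lambda":
                # hard switch: drift gate closed
                if f <= GATE_LEVEL:
                    in_phase3 = True
            if in_phase3:
                nxt = ar1.mu + ar1.rho * (f - ar1.mu) + ar1.s * rng.standard_normal()
            else:
                sd = sigma_eps(f, t, dist, future, floor=0.0)
                nxt = f - float(decrement(theta, f)) + sd * rng.standard_normal()
            nxt = max(nxt, floor)
            traj[k, t] = nxt
            phase_at[k, t] = "III" if in_phase3 else "II"
            if (
                not in_phase3
                and config.phase3_rule == "lambda"
                and prev1 > prev2
                and nxt > prev1
                and prev2 < LAMBDA_CEILING
                and prev1 < LAMBDA_CEILING
                and nxt < LAMBDA_CEILING
            ):
                in_phase3 = True  # post-transition pattern met at this step
            prev2, prev1 = prev1, nxt
            f = nxt
    years = [future.mid_year(t) for t in range(n_fut)]
    qt = summarize_trajectories(traj, years)
    hi, lo = make_variants(qt, floor)
    return TrajectorySet(
        region_id=series.region_id,
        grid=future,
        trajectories=traj,
        phase_at=phase_at,
        quantiles=qt,
        variant_high=hi,
        variant_low=lo,
    )


def project_panel(
    panel: TFRPanel,
    phases: dict[str, PhaseAssignment],
    posterior: PosteriorSample,
    ar1: AR1Params,
    config: ProjectionConfig,
) -> tuple[dict[str, TrajectorySet], pd.DataFrame]:
    """Project every region of a panel (national series included as its own
    region) and build a combined long-format report.

    Returns the per-region trajectory sets and a DataFrame with columns
    (region_id, year, statistic, value) covering mean, sd, the nine
    quantiles and the high/low variants.  Per-region results are
    independent of panel ordering: each region uses its own seed stream
    keyed by a stable hash of its id.
    """
    results: dict[str, TrajectorySet] = {}
    rows = []
    for s in panel.series:
        offset = _region_seed_offset(s.region_id)
        ts = simulate_region(s, phases[s.region_id], posterior, ar1, config, seed_offset=offset)
        results[s.region_id] = ts
        qt = ts.quantiles
        for t, year in enumerate(qt.years):
            rows.append((s.region_id, int(year), "mean", qt.mean[t]))
            rows.append((s.region_id, int(year), "sd", qt.sd[t]))
            for j, p in enumerate(QUANTILE_PROBS):
                rows.append((s.region_id, int(year), f"q{100 * p:g}", qt.quantiles[t, j]))
            rows.append((s.region_id, int(year), "high_variant", ts.variant_high[t]))
            rows.append((s.region_id, int(year), "low_variant", ts.variant_low[t]))
    report = pd.DataFrame(rows, columns=["region_id", "year", "statistic", "value"])
    return results, report


def _region_seed_offset(region_id: str) -> int:
    """Stable, order-free per-region stream offset (< 2^31)."""
    h = 0
    for ch in region_id:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h
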