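"""Bayesian hierarchical estimation of the fertility-transition model.

The transition (Phase II) observations of every region enter one joint
posterior: region-level transformed parameters (d*, Δ4*, γ) are
exchangeable normal draws governed by national-level hyperparameters
{χ, ψ, Δ_4, δ_4, α, δ}; distortion parameters {m_τ, s_τ, σ0, S, a, b,
c_1975} are shared across regions; regions whose transition began before
the observation window carry their onset level U_c as an extra parameter
with a uniform prior on (min{5.5, max_t f_t}, 8.8).

Sampling is single-site Gaussian random-walk Metropolis within a Gibbs
sweep over all scalar coordinates — slower per effective draw than a
gradient sampler but simple to audit at this parameter count (tens of
scalars).  Proposal scales adapt toward 44% acceptance during burn-in and
are frozen afterwards; runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MCMCConfig, PriorConfig
from .decline import (
    DeclineParams,
    DistortionParams,
    HierarchyParams,
    SIGMA_FLOOR,
    decrement,
    from_transformed,
    sigma_eps,
)
from .exceptions import ModelError
from .periods import TFRPanel, TFRSeries
from .phases import PhaseAssignment

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SLOPE = 2.0 * math.log(9.0)

_HYPER_NAMES = (
    "chi", "psi", "Delta4_mean", "delta4_sd",
    "alpha1", "alpha2", "alpha3", "delta_sd1", "delta_sd2", "delta_sd3",
)
_DIST_NAMES = ("m_tau", "s_tau", "sigma0", "S", "a", "b", "c1975")
_THETA_COORDS = ("d_star", "Delta4_star", "gamma1", "gamma2", "gamma3")


# --------------------------------------------------------------------------
# model state and public densities


@dataclass(frozen=True)
class RegionState:
    """One region's transformed transition parameters."""

    d_star: float
    delta4_star: float
    gamma: tuple[float, float, float]
    U: float
    #: True when U is a sampled parameter (onset before observation).
    U_sampled: bool = False

    def to_decline_params(self) -> DeclineParams:
        return from_transformed(self.d_star, self.delta4_star, np.array(self.gamma), self.U)


@dataclass(frozen=True)
class ModelState:
    """Full parameter state: per-region, hierarchy and distortion levels."""

    regions: dict[str, RegionState]
    hyper: HierarchyParams
    dist: DistortionParams


def _norm_logpdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -_LOG_SQRT_2PI - math.log(sd) - 0.5 * z * z


def _uniform_logpdf(x: float, lo: float, hi: float) -> float:
    if lo < x < hi:
        return -math.log(hi - lo)
    return -math.inf


def phase2_loglik(
    series: TFRSeries,
    phases: PhaseAssignment,
    theta: DeclineParams,
    dist: DistortionParams,
) -> float:
    """Log-likelihood of one region's observed transition steps.

    Each step t -> t+1 with t in [τ, λ) contributes the log-density of the
    distortion ε_t = f_{t+1} − f_t + d_t, which is N(m_τ, s_τ²) at the
    observed onset step and N(0, σ(f_t)²) otherwise.
    """
    steps = phases.phase2_step_indices(len(series))
    if not steps:
        raise ModelError(
            f"region {series.region_id!r} has no transition steps; "
            "it enters the post-transition model only"
        )
    v = series.values
    ll = 0.0
    for t in steps:
        eps = float(v[t + 1] - v[t] + decrement(theta, float(v[t])))
        if phases.tau_observed and t == phases.tau:
            ll += _norm_logpdf(eps, dist.m_tau, dist.s_tau)
        else:
            ll += _norm_logpdf(eps, 0.0, sigma_eps(float(v[t]), t, dist, series.grid))
    return float(ll)


def log_prior(
    state: ModelState,
    config: MCMCConfig,
    U_bounds: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Joint log-prior of a model state; −inf outside any support.

    ``U_bounds`` maps region ids with sampled onset levels to their uniform
    supports (min{5.5, max_t f_t}, 8.8); when omitted, only the global
    upper cap is enforced for those regions.
    """
    pr: PriorConfig = config.priors
    h = state.hyper
    d = state.dist
    lp = 0.0
    lp += _uniform_logpdf(h.chi, *pr.chi)
    lp += _uniform_logpdf(h.psi, *pr.psi)
    lp += _uniform_logpdf(h.Delta4_mean, *pr.Delta4_mean)
    lp += _uniform_logpdf(h.delta4_sd, *pr.delta4_sd)
    for i in range(3):
        lp += _uniform_logpdf(h.alpha[i], *pr.alpha)
        lp += _uniform_logpdf(h.delta_sd[i], *pr.delta_sd)
    lp += _uniform_logpdf(d.m_tau, *pr.m_tau)
    lp += _uniform_logpdf(d.s_tau, *pr.s_tau)
    lp += _uniform_logpdf(d.sigma0, *pr.sigma0)
    lp += _uniform_logpdf(d.S, *pr.S)
    lp += _uniform_logpdf(d.a, *pr.a)
    lp += _uniform_logpdf(d.b, *pr.b)
    lp += _uniform_logpdf(d.c1975, *pr.c1975)
    if not math.isfinite(lp):
        return -math.inf
    for rid, rs in state.regions.items():
        lp += _norm_logpdf(rs.d_star, h.chi, h.psi)
        lp += _norm_logpdf(rs.delta4_star, h.Delta4_mean, h.delta4_sd)
        for i in range(3):
            lp += _norm_logpdf(rs.gamma[i], h.alpha[i], h.delta_sd[i])
        if rs.U_sampled:
            if U_bounds is not None and rid in U_bounds:
                lp += _uniform_logpdf(rs.U, *U_bounds[rid])
            elif not rs.U < pr.U_upper:
                return -math.inf
    if not math.isfinite(lp):
        return -math.inf
    return float(lp)


# --------------------------------------------------------------------------
# fast scalar kernels (hot path of the single-site sampler)


def _logistic(x: float) -> float:
    if x >= 0.0:
        if x > 700.0:
            return 1.0
        e = math.exp(-x)
        return 1.0 / (1.0 + e)
    if x < -700.0:
        return 0.0
    e = math.exp(x)
    return e / (1.0 + e)


def _raw_theta(d_star: float, d4_star: float, g1: float, g2: float, g3: float, U: float):
    """Inverse transform to (d1, d3, d4, dc, U) or None when U <= Δ4."""
    dc = 0.25 + 2.25 * _logistic(d_star)
    d4 = 1.0 + 1.5 * _logistic(d4_star)
    if U <= d4:
        return None
    gm = max(g1, g2, g3)
    e1 = math.exp(g1 - gm)
    e2 = math.exp(g2 - gm)
    e3 = math.exp(g3 - gm)
    tot = e1 + e2 + e3
    rem = U - d4
    return (e1 / tot * rem, e3 / tot * rem, d4, dc, U)


def _region_loglik(f0, f1, start_pos, pre75, raw, dv):
    """Transition log-likelihood of one region; returns (ll, residuals).

    ``raw`` is (d1, d3, d4, dc, U); ``dv`` the 7-tuple of distortion values
    (m_tau, s_tau, sigma0, S, a, b, c1975).  Plain-float loop: the per-region
    step count is ~10, below the size where vectorization pays off.
    """
    d1, d3, d4, dc, U = raw
    m_tau, s_tau, sigma0, S, a, b, c1975 = dv
    s1 = _SLOPE / d1
    s2 = _SLOPE / d3
    ll = 0.0
    resid = []
    for i, f in enumerate(f0):
        if f > 1.0:
            d = -dc * _logistic(s1 * (f - U + 0.5 * d1)) + dc * _logistic(s2 * (f - d4 - 0.5 * d3))
        else:
            d = 0.0
        e = f1[i] - f + d
        resid.append(e)
        if i == start_pos:
            sd = s_tau
            mu = m_tau
        else:
            sd = sigma0 + (f - S) * (-a if f >= S else b)
            if sd < SIGMA_FLOOR:
                sd = SIGMA_FLOOR
            if pre75[i]:
                sd *= c1975
            mu = 0.0
        z = (e - mu) / sd
        ll += -_LOG_SQRT_2PI - math.log(sd) - 0.5 * z * z
    return ll, resid


# --------------------------------------------------------------------------
# posterior sample container


@dataclass
class PosteriorSample:
    """Retained MCMC draws of all scalar parameters.

    ``draws`` is (n_draws, n_params) in ``param_names`` order; per-draw
    chain id, iteration index and log-posterior are kept alongside, plus
    the metadata needed to rebuild a full :class:`ModelState` per draw.
    """

    draws: np.ndarray
    param_names: list[str]
    chain_id: np.ndarray
    iteration: np.ndarray
    log_posterior: np.ndarray
    region_ids: list[str]
    fixed_U: dict[str, float]
    U_bounds: dict[str, tuple[float, float]]
    acceptance: dict[str, float]
    config: MCMCConfig
    warnings_: list[str]

    def __post_init__(self) -> None:
        self._idx = {n: i for i, n in enumerate(self.param_names)}

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self._idx[name]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.param_names)
        df.insert(0, "chain", self.chain_id)
        df.insert(1, "iteration", self.iteration)
        df["log_posterior"] = self.log_posterior
        return df

    def state_at(self, i: int) -> ModelState:
        """Rebuild the full model state of draw ``i``."""
        g = lambda n: float(self.draws[i, self._idx[n]])
        regions = {}
        for rid in self.region_ids:
            sampled = rid not in self.fixed_U
            U = g(f"U[{rid}]") if sampled else self.fixed_U[rid]
            regions[rid] = RegionState(
                d_star=g(f"d_star[{rid}]"),
                delta4_star=g(f"Delta4_star[{rid}]"),
                gamma=(g(f"gamma1[{rid}]"), g(f"gamma2[{rid}]"), g(f"gamma3[{rid}]")),
                U=U,
                U_sampled=sampled,
            )
        hyper = HierarchyParams(
            chi=g("chi"), psi=g("psi"),
            Delta4_mean=g("Delta4_mean"), delta4_sd=g("delta4_sd"),
            alpha=(g("alpha1"), g("alpha2"), g("alpha3")),
            delta_sd=(g("delta_sd1"), g("delta_sd2"), g("delta_sd3")),
        )
        dist = DistortionParams(
            m_tau=g("m_tau"), s_tau=g("s_tau"), sigma0=g("sigma0"),
            S=g("S"), a=g("a"), b=g("b"), c1975=g("c1975"),
        )
        return ModelState(regions=regions, hyper=hyper, dist=dist)

    def theta_at(self, i: int, region_id: str) -> DeclineParams:
        return self.state_at(i).regions[region_id].to_decline_params()

    @classmethod
    def from_states(
        cls,
        states: list[ModelState],
        config: MCMCConfig | None = None,
    ) -> "PosteriorSample":
        """Build a sample from explicit model states (e.g. known truth), so
        the projection machinery can be driven by chosen parameters."""
        if not states:
            raise ModelError("need at least one state")
        region_ids = list(states[0].regions)
        names: list[str] = []
        for rid in region_ids:
            names += [f"{c}[{rid}]" for c in _THETA_COORDS]
        fixed_U: dict[str, float] = {}
        for rid, rs in states[0].regions.items():
            if rs.U_sampled:
                names.append(f"U[{rid}]")
            else:
                fixed_U[rid] = rs.U
        names += list(_HYPER_NAMES) + list(_DIST_NAMES)
        rows = []
        for st in states:
            row = []
            for rid in region_ids:
                rs = st.regions[rid]
                row += [rs.d_star, rs.delta4_star, *rs.gamma]
            for rid in region_ids:
                if st.regions[rid].U_sampled:
                    row.append(st.regions[rid].U)
            h, d = st.hyper, st.dist
            row += [h.chi, h.psi, h.Delta4_mean, h.delta4_sd, *h.alpha, *h.delta_sd]
            row += [d.m_tau, d.s_tau, d.sigma0, d.S, d.a, d.b, d.c1975]
            rows.append(row)
        n = len(rows)
        return cls(
            draws=np.array(rows, dtype=float),
            param_names=names,
            chain_id=np.zeros(n, dtype=int),
            iteration=np.arange(n),
            log_posterior=np.full(n, np.nan),
            region_ids=region_ids,
            fixed_U=fixed_U,
            U_bounds={},
            acceptance={},
            config=config or MCMCConfig(),
            warnings_=[],
        )


# --------------------------------------------------------------------------
# the sampler


class _Param:
    __slots__ = ("name", "kind", "region", "coord", "lo", "hi", "init")

    def __init__(self, name, kind, region=None, coord=None, lo=-math.inf, hi=math.inf, init=0.0):
        self.name = name
        self.kind = kind          # "theta" | "U" | "hyper" | "dist"
        self.region = region      # region position for theta/U
        self.coord = coord        # 0..4 for theta coords; name for hyper/dist
        self.lo = lo
        self.hi = hi
        self.init = init


_HYPER_INITS = {
    "chi": 0.0, "psi": 0.5, "Delta4_mean": 0.0, "delta4_sd": 0.5,
    "alpha1": 0.0, "alpha2": 0.0, "alpha3": 0.0,
    "delta_sd1": 0.5, "delta_sd2": 0.5, "delta_sd3": 0.5,
}
_DIST_INITS = {
    "m_tau": 0.0, "s_tau": 0.25, "sigma0": 0.1, "S": 4.5,
    "a": 0.05, "b": 0.05, "c1975": 1.25,
}


class Phase2Sampler:
    """Metropolis-within-Gibbs sampler for the hierarchical Phase II model."""

    def __init__(self, panel: TFRPanel, phases: dict[str, PhaseAssignment], config: MCMCConfig):
        self.config = config
        pr = config.priors
        self.region_ids: list[str] = []
        self.f0: list[list[float]] = []
        self.f1: list[list[float]] = []
        self.start_pos: list[int] = []
        self.pre75: list[list[bool]] = []
        self.fixed_U: dict[str, float] = {}
        self.U_bounds: dict[str, tuple[float, float]] = {}
        u_sampled: list[bool] = []
        u_init: list[float] = []
        for s in panel.series:
            pa = phases[s.region_id]
            steps = pa.phase2_step_indices(len(s))
            if not steps:
                continue  # purely post-transition region: AR(1) only
            self.region_ids.append(s.region_id)
            self.f0.append([float(s.values[t]) for t in steps])
            self.f1.append([float(s.values[t + 1]) for t in steps])
            self.start_pos.append(
                steps.index(pa.tau) if pa.tau_observed and pa.tau in steps else -1
            )
            self.pre75.append([s.grid.start_of(t) <= 1970 for t in steps])
            if pa.tau_observed:
                u_sampled.append(False)
                self.fixed_U[s.region_id] = float(s.values[pa.tau])
                u_init.append(self.fixed_U[s.region_id])
            else:
                u_sampled.append(True)
                lo = min(pr.U_lower_cap, float(s.values.max()))
                hi = pr.U_upper
                self.U_bounds[s.region_id] = (lo, hi)
                u_init.append(0.5 * (lo + hi))
        if not self.region_ids:
            raise ModelError("no region has Phase II transition steps; nothing to fit")
        self.n_regions = len(self.region_ids)
        self._u_sampled = u_sampled
        self._u_init = u_init

        # flattened parameter table
        params: list[_Param] = [
            _Param(f"{c}[{rid}]", "theta", region=r, coord=ci)
            for r, rid in enumerate(self.region_ids)
            for ci, c in enumerate(_THETA_COORDS)
        ]
        for r, rid in enumerate(self.region_ids):
            if u_sampled[r]:
                lo, hi = self.U_bounds[rid]
                params.append(_Param(f"U[{rid}]", "U", region=r, lo=lo, hi=hi, init=u_init[r]))
        hyper_bounds = {
            "chi": pr.chi, "psi": pr.psi, "Delta4_mean": pr.Delta4_mean,
            "delta4_sd": pr.delta4_sd,
            "alpha1": pr.alpha, "alpha2": pr.alpha, "alpha3": pr.alpha,
            "delta_sd1": pr.delta_sd, "delta_sd2": pr.delta_sd, "delta_sd3": pr.delta_sd,
        }
        for n in _HYPER_NAMES:
            lo, hi = hyper_bounds[n]
            params.append(_Param(n, "hyper", coord=n, lo=lo, hi=hi, init=_HYPER_INITS[n]))
        dist_bounds = {
            "m_tau": pr.m_tau, "s_tau": pr.s_tau, "sigma0": pr.sigma0,
            "S": pr.S, "a": pr.a, "b": pr.b, "c1975": pr.c1975,
        }
        for n in _DIST_NAMES:
            lo, hi = dist_bounds[n]
            params.append(_Param(n, "dist", coord=n, lo=lo, hi=hi, init=_DIST_INITS[n]))
        self.params = params
        self.param_names = [p.name for p in params]
        self._name_idx = {p.name: i for i, p in enumerate(params)}
        for fp in config.fixed_params:
            if fp not in self._name_idx:
                raise ModelError(f"fixed parameter {fp!r} is not a model parameter")

        # concatenated step arrays for the vectorized distortion update
        lens = [len(f) for f in self.f0]
        self._slices = np.concatenate([[0], np.cumsum(lens)])
        self._all_f0 = np.concatenate([np.array(f) for f in self.f0])
        self._all_pre75 = np.concatenate([np.array(p) for p in self.pre75])
        mask = np.zeros(len(self._all_f0), dtype=bool)
        for r, sp in enumerate(self.start_pos):
            if sp >= 0:
                mask[self._slices[r] + sp] = True
        self._all_start = mask

        # hyper lookup tables for the hot loop: theta coord -> (mu, sd) param
        # indices, and hyper name -> (coord, role)
        gi = self._name_idx
        self._coord_hyper = [
            (gi["chi"], gi["psi"]),
            (gi["Delta4_mean"], gi["delta4_sd"]),
            (gi["alpha1"], gi["delta_sd1"]),
            (gi["alpha2"], gi["delta_sd2"]),
            (gi["alpha3"], gi["delta_sd3"]),
        ]
        self._hyper_role = {
            "chi": (0, "mu"), "psi": (0, "sd"),
            "Delta4_mean": (1, "mu"), "delta4_sd": (1, "sd"),
            "alpha1": (2, "mu"), "delta_sd1": (2, "sd"),
            "alpha2": (3, "mu"), "delta_sd2": (3, "sd"),
            "alpha3": (4, "mu"), "delta_sd3": (4, "sd"),
        }

    # -- state bookkeeping -------------------------------------------------

    def _init_state(self, rng: np.random.Generator) -> np.ndarray:
        x = np.array([p.init for p in self.params], dtype=float)
        for i, p in enumerate(self.params):
            if p.name in self.config.fixed_params:
                x[i] = float(self.config.fixed_params[p.name])
                continue
            jit = 0.1 * rng.standard_normal()
            if math.isfinite(p.lo) and math.isfinite(p.hi):
                width = p.hi - p.lo
                x[i] = float(np.clip(x[i] + jit * width * 0.2, p.lo + 1e-3 * width, p.hi - 1e-3 * width))
            else:
                x[i] += jit
        return x

    def _theta_raw(self, x: np.ndarray, r: int):
        base = 5 * r
        if self._u_sampled[r]:
            U = x[self._name_idx[f"U[{self.region_ids[r]}]"]]
        else:
            U = self._u_init[r]
        return _raw_theta(x[base], x[base + 1], x[base + 2], x[base + 3], x[base + 4], U)

    def _dist_values(self, x: np.ndarray) -> tuple:
        return tuple(x[self._name_idx[n]] for n in _DIST_NAMES)

    def _region_ll(self, x: np.ndarray, r: int, dv: tuple):
        raw = self._theta_raw(x, r)
        if raw is None:
            return -math.inf, None
        return _region_loglik(self.f0[r], self.f1[r], self.start_pos[r], self.pre75[r], raw, dv)

    def _region_logprior(self, x: np.ndarray, r: int) -> float:
        base = 5 * r
        h = {n: x[self._name_idx[n]] for n in _HYPER_NAMES}
        lp = _norm_logpdf(x[base], h["chi"], h["psi"])
        lp += _norm_logpdf(x[base + 1], h["Delta4_mean"], h["delta4_sd"])
        lp += _norm_logpdf(x[base + 2], h["alpha1"], h["delta_sd1"])
        lp += _norm_logpdf(x[base + 3], h["alpha2"], h["delta_sd2"])
        lp += _norm_logpdf(x[base + 4], h["alpha3"], h["delta_sd3"])
        return lp

    def _dist_ll_vec(self, resid: np.ndarray, dv: tuple) -> np.ndarray:
        """Per-step log-densities given residuals and distortion values."""
        m_tau, s_tau, sigma0, S, a, b, c1975 = dv
        f = self._all_f0
        sd = sigma0 + (f - S) * np.where(f >= S, -a, b)
        np.maximum(sd, SIGMA_FLOOR, out=sd)
        sd = np.where(self._all_pre75, sd * c1975, sd)
        sd = np.where(self._all_start, s_tau, sd)
        mu = np.where(self._all_start, m_tau, 0.0)
        z = (resid - mu) / sd
        return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * z * z

    def log_posterior(self, x: np.ndarray) -> float:
        """Full log-posterior at a flat state (used for audits and tests)."""
        dv = self._dist_values(x)
        lp = self._flat_logprior(x)
        if not math.isfinite(lp):
            return -math.inf
        for r in range(self.n_regions):
            ll, _ = self._region_ll(x, r, dv)
            lp += ll
        return lp

    def _flat_logprior(self, x: np.ndarray) -> float:
        lp = 0.0
        for i, p in enumerate(self.params):
            if p.kind in ("hyper", "dist", "U"):
                lp += _uniform_logpdf(x[i], p.lo, p.hi)
        if not math.isfinite(lp):
            return -math.inf
        for r in range(self.n_regions):
            lp += self._region_logprior(x, r)
        return lp

    # -- main loop ---------------------------------------------------------

    def run(self) -> PosteriorSample:
        cfg = self.config
        all_draws, all_chain, all_iter, all_lp = [], [], [], []
        acc_total: dict[str, list[int]] = {p.name: [0, 0] for p in self.params}
        warns: list[str] = []
        for chain in range(cfg.chains):
            rng = np.random.default_rng([int(cfg.seed), chain])
            d, it, lp, acc = self._run_chain(chain, rng, warns)
            all_draws.append(d)
            all_chain.append(np.full(d.shape[0], chain))
            all_iter.append(it)
            all_lp.append(lp)
            for n, (a, t) in acc.items():
                acc_total[n][0] += a
                acc_total[n][1] += t
        free = [
            p.name for p in self.params
            if p.name not in cfg.fixed_params and acc_total[p.name][1] > 0
        ]
        for n in free:
            if acc_total[n][0] == 0:
                msg = f"no accepted proposals for {n!r} after burn-in"
                warns.append(msg)
                warnings.warn(msg, stacklevel=2)
        acceptance = {
            n: (a / t if t else float("nan")) for n, (a, t) in acc_total.items()
        }
        return PosteriorSample(
            draws=np.vstack(all_draws),
            param_names=self.param_names,
            chain_id=np.concatenate(all_chain),
            iteration=np.concatenate(all_iter),
            log_posterior=np.concatenate(all_lp),
            region_ids=self.region_ids,
            fixed_U=dict(self.fixed_U),
            U_bounds=dict(self.U_bounds),
            acceptance=acceptance,
            config=cfg,
            warnings_=warns,
        )

    def _run_chain(self, chain: int, rng: np.random.Generator, warns: list[str]):
        cfg = self.config
        x = self._init_state(rng)
        dv = self._dist_values(x)

        region_ll = np.empty(self.n_regions)
        resid = np.empty(len(self._all_f0))
        for r in range(self.n_regions):
            ll, e = self._region_ll(x, r, dv)
            if not math.isfinite(ll):
                raise ModelError(f"non-finite initial likelihood for region {self.region_ids[r]!r}")
            region_ll[r] = ll
            resid[self._slices[r]:self._slices[r + 1]] = e

        free_idx = [i for i, p in enumerate(self.params) if p.name not in cfg.fixed_params]
        log_scale = {i: math.log(cfg.proposal_scale) for i in free_idx}
        win_acc = {i: 0 for i in free_idx}
        win_tot = {i: 0 for i in free_idx}
        post_acc = {self.params[i].name: [0, 0] for i in free_idx}

        # cached hyper sums are recomputed on demand; hyper updates only touch
        # the region-prior terms, never the data likelihood
        draws, iters, lps = [], [], []
        for it in range(cfg.iterations):
            in_burn = it < cfg.burn_in
            for i in free_idx:
                p = self.params[i]
                prop = x[i] + math.exp(log_scale[i]) * rng.standard_normal()
                accept = False
                if p.kind in ("hyper", "dist", "U") and not (p.lo < prop < p.hi):
                    pass  # out of uniform support: reject
                elif p.kind == "theta":
                    r = p.region
                    old, x[i] = x[i], prop
                    new_ll, new_e = self._region_ll(x, r, dv)
                    x[i] = old
                    if math.isfinite(new_ll):
                        mh, sh = self._coord_hyper[p.coord]
                        mu, sd = x[mh], x[sh]
                        dprior = _norm_logpdf(prop, mu, sd) - _norm_logpdf(old, mu, sd)
                        if math.log(rng.random()) < new_ll - region_ll[r] + dprior:
                            x[i] = prop
                            region_ll[r] = new_ll
                            resid[self._slices[r]:self._slices[r + 1]] = new_e
                            accept = True
                elif p.kind == "U":
                    r = p.region
                    old, x[i] = x[i], prop
                    new_ll, new_e = self._region_ll(x, r, dv)
                    x[i] = old
                    if math.isfinite(new_ll) and math.log(rng.random()) < new_ll - region_ll[r]:
                        x[i] = prop
                        region_ll[r] = new_ll
                        resid[self._slices[r]:self._slices[r + 1]] = new_e
                        accept = True
                elif p.kind == "hyper":
                    coord, role = self._hyper_role[p.coord]
                    vals = x[coord: 5 * self.n_regions: 5]
                    mh, sh = self._coord_hyper[coord]
                    mu, sd = x[mh], x[sh]
                    if role == "mu":
                        delta = 0.5 * (((vals - mu) ** 2).sum() - ((vals - prop) ** 2).sum()) / (sd * sd)
                    else:
                        n_r = self.n_regions
                        sq = ((vals - mu) ** 2).sum()
                        delta = (
                            n_r * (math.log(sd) - math.log(prop))
                            - 0.5 * sq / (prop * prop)
                            + 0.5 * sq / (sd * sd)
                        )
                    if math.log(rng.random()) < delta:
                        x[i] = prop
                        accept = True
                else:  # dist
                    old_dv = dv
                    old_vec = self._dist_ll_vec(resid, old_dv)
                    old, x[i] = x[i], prop
                    new_dv = self._dist_values(x)
                    new_vec = self._dist_ll_vec(resid, new_dv)
                    x[i] = old
                    if math.log(rng.random()) < float(new_vec.sum() - old_vec.sum()):
                        x[i] = prop
                        dv = new_dv
                        region_ll = np.add.reduceat(new_vec, self._slices[:-1])
                        accept = True
                win_tot[i] += 1
                win_acc[i] += accept
                if not in_burn:
                    post_acc[p.name][0] += accept
                    post_acc[p.name][1] += 1
            if in_burn and (it + 1) % cfg.adapt_every == 0:
                for i in free_idx:
                    if win_tot[i]:
                        rate = win_acc[i] / win_tot[i]
                        log_scale[i] += rate - cfg.target_acceptance
                        win_acc[i] = 0
                        win_tot[i] = 0
            if not in_burn and (it - cfg.burn_in) % cfg.thin == 0:
                lp = float(region_ll.sum()) + self._flat_logprior(x)
                if math.isnan(lp):
                    raise ModelError(f"NaN log-posterior at iteration {it}, state {dict(zip(self.param_names, x))}")
                draws.append(x.copy())
                iters.append(it)
                lps.append(lp)
        return np.array(draws), np.array(iters), np.array(lps), post_acc


def run_mcmc(
    panel: TFRPanel,
    phases: dict[str, PhaseAssignment],
    config: MCMCConfig,
) -> PosteriorSample:
    """Sample the joint posterior of the hierarchical transition model.

    Regions without any transition step are skipped (they enter the
    post-transition AR(1) fit only); an error is raised when no region at
    all has transition steps.  Deterministic given ``config.seed``.
    """
    return Phase2Sampler(panel, phases, config).run()


# --------------------------------------------------------------------------
# posterior summaries and convergence diagnostics


def _batch_means_se(by_chain: list[np.ndarray]) -> float:
    """Time-series standard error of the mean via the batch-means method."""
    bms = []
    n_total = 0
    for x in by_chain:
        n = len(x)
        n_total += n
        b = max(1, int(math.sqrt(n)))
        nb = n // b
        if nb < 2:
            continue
        bm = x[: nb * b].reshape(nb, b).mean(axis=1)
        bms.append((b, bm))
    if not bms or sum(len(bm) for _, bm in bms) < 2:
        return float("nan")
    b0 = bms[0][0]
    allbm = np.concatenate([bm for _, bm in bms])
    return float(math.sqrt(b0 * allbm.var(ddof=1) / n_total))


def summarize_posterior(sample: PosteriorSample) -> pd.DataFrame:
    """Per-parameter posterior summary.

    Columns: Mean, SD, Naive SE (sd/√n), Time-series SE (batch means) and
    the 2.5/25/50/75/97.5% quantiles.
    """
    if sample.n_draws == 0:
        raise ModelError("empty posterior sample")
    rows = []
    chains = np.unique(sample.chain_id)
    for j, name in enumerate(sample.param_names):
        col = sample.draws[:, j]
        n = len(col)
        sd = float(col.std(ddof=1)) if n > 1 else 0.0
        by_chain = [col[sample.chain_id == c] for c in chains]
        ts = _batch_means_se(by_chain) if sd > 0 else 0.0
        q = np.quantile(col, [0.025, 0.25, 0.50, 0.75, 0.975])
        rows.append({
            "parameter": name,
            "Mean": float(col.mean()),
            "SD": sd,
            "Naive SE": sd / math.sqrt(n),
            "Time-series SE": ts,
            "2.5%": q[0], "25%": q[1], "50%": q[2], "75%": q[3], "97.5%": q[4],
        })
    return pd.DataFrame(rows).set_index("parameter")


def _split_chains(by_chain: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for x in by_chain:
        h = len(x) // 2
        out.extend([x[:h], x[h: 2 * h]])
    return out


def _rhat(by_chain: list[np.ndarray]) -> float:
    seqs = _split_chains(by_chain)
    L = min(len(s) for s in seqs)
    if L < 2:
        return float("nan")
    seqs = [s[:L] for s in seqs]
    W = float(np.mean([s.var(ddof=1) for s in seqs]))
    if W == 0:
        return float("nan")
    means = np.array([s.mean() for s in seqs])
    B_over_n = means.var(ddof=1)
    var_hat = (L - 1) / L * W + B_over_n
    return float(math.sqrt(var_hat / W))


def _ess(by_chain: list[np.ndarray]) -> float:
    """Effective sample size via combined-chain autocorrelations with
    Geyer's initial-positive-sequence truncation."""
    m = len(by_chain)
    L = min(len(c) for c in by_chain)
    if L < 4:
        return float("nan")
    chains = np.array([c[:L] for c in by_chain])
    W = float(np.mean(chains.var(axis=1, ddof=1)))
    means = chains.mean(axis=1)
    var_hat = (L - 1) / L * W + (means.var(ddof=1) if m > 1 else 0.0)
    if var_hat == 0:
        return float("nan")
    # per-chain autocovariances via FFT
    n_fft = 1 << (2 * L - 1).bit_length()
    acov = np.zeros((m, L))
    for k in range(m):
        xc = chains[k] - chains[k].mean()
        fx = np.fft.rfft(xc, n_fft)
        ac = np.fft.irfft(fx * np.conj(fx), n_fft)[:L].real / L
        acov[k] = ac
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_hat
    rho[0] = 1.0
    # sum consecutive pairs until the first negative pair sum
    pair_sum = 0.0
    t = 0
    while t + 1 < L:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair_sum += pair
        t += 2
    # tau = 1 + 2*sum_{t>=1} rho_t = 2*sum_pairs - 1 (the pairs include rho_0)
    tau = max(2.0 * pair_sum - 1.0, 1e-9)
    return float(m * L / tau)


def convergence_diagnostics(sample: PosteriorSample, rhat_warn: float = 1.1) -> pd.DataFrame:
    """Split-R̂ and effective sample size per scalar parameter.

    Requires at least two chains; a warning is emitted when any R̂ exceeds
    ``rhat_warn``.  Parameters with zero posterior variance (fixed or stuck)
    report NaN.
    """
    if sample.n_chains < 2:
        raise ModelError("convergence diagnostics need >= 2 chains")
    chains = np.unique(sample.chain_id)
    rows = []
    for j, name in enumerate(sample.param_names):
        col = sample.draws[:, j]
        by_chain = [col[sample.chain_id == c] for c in chains]
        rows.append({"parameter": name, "rhat": _rhat(by_chain), "ess": _ess(by_chain)})
    df = pd.DataFrame(rows).set_index("parameter")
    bad = df[df["rhat"] > rhat_warn]
    if len(bad):
        warnings.warn(
            f"{len(bad)} parameter(s) with split-Rhat > {rhat_warn}: "
            f"{list(bad.index[:5])}", stacklevel=2,
        )
    return df
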