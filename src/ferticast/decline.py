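"""Phase II generative model primitives.

During the fertility transition the TFR follows a random walk with a
level-dependent drift,

    f_{c,t+1} = f_{c,t} − d_{c,t} + ε_{c,t},

where the expected five-year decrement d is a *double-logistic* function of
the current TFR level, ε is a Gaussian distortion whose standard deviation
σ(f) peaks at an intermediate TFR level S and is inflated before 1975, and
the region parameter vector θ_c = (Δ_c1..Δ_c4, d_c) partitions the
transition's TFR range: U_c = ΣΔ_ci is the onset level, Δ_c4 the
end-of-transition level, and d_c caps the pace of decline.

Region parameters live on the hierarchy through logit-type transforms
(d_c on (0.25, 2.5), Δ_c4 on (1, 2.5)) and a softmax share vector for
(Δ_c1, Δ_c2, Δ_c3); the transforms here are exact inverses of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterRangeError
from .periods import PeriodGrid

# Logistic steepness constant: each logistic rises from 10% to 90% of its
# height over its Delta interval, i.e. slope 2·ln(p)/Delta with p = 9.
P_CONST = 9.0
_SLOPE = 2.0 * math.log(P_CONST)

# Open ranges of the logit-type transforms.
D_LO, D_HI = 0.25, 2.5
DELTA4_LO, DELTA4_HI = 1.0, 2.5

# Drift gate: no systematic decline once the TFR falls to 1 child or below.
DECREMENT_GATE = 1.0

# Floor of the distortion sd (children); the linear sd model is otherwise
# improper at extreme TFR levels.
SIGMA_FLOOR = 0.01

# Last calendar year (period start) with inflated distortion variance.
PRE1975_LAST_START = 1970


@dataclass(frozen=True)
class DeclineParams:
    """Region-specific double-logistic parameters θ_c.

    delta : (Δ_c1, Δ_c2, Δ_c3, Δ_c4), non-negative TFR increments whose sum
        U_c is the transition onset level (children per woman).
    d_max : d_c, maximum five-year decline (children per woman per period).
    """

    delta: tuple[float, float, float, float]
    d_max: float

    def __post_init__(self) -> None:
        if len(self.delta) != 4 or any(d < 0 for d in self.delta):
            raise ParameterRangeError(f"delta must be 4 non-negative values, got {self.delta}")
        if not np.isfinite(self.d_max) or self.d_max <= 0:
            raise ParameterRangeError(f"d_max must be positive, got {self.d_max}")

    @property
    def onset_level(self) -> float:
        """U_c = ΣΔ_ci, the TFR at transition onset."""
        return float(sum(self.delta))


@dataclass(frozen=True)
class DistortionParams:
    """Distortion distribution parameters.

    m_tau, s_tau : mean and sd of the onset-period distortion.
    sigma0 : maximum distortion sd, reached at TFR level S.
    a, b : linear sd decrease per child above / below S.
    c1975 : multiplicative sd inflation for periods before 1975.
    """

    m_tau: float = 0.0
    s_tau: float = 0.25
    sigma0: float = 0.1
    S: float = 4.5
    a: float = 0.01
    b: float = 0.01
    c1975: float = 1.25

    def __post_init__(self) -> None:
        if self.s_tau <= 0 or self.sigma0 <= 0:
            raise ParameterRangeError("s_tau and sigma0 must be > 0")
        if self.a < 0 or self.b < 0:
            raise ParameterRangeError("sd multipliers a, b must be >= 0")
        if self.c1975 <= 0:
            raise ParameterRangeError("c1975 must be > 0")


@dataclass(frozen=True)
class HierarchyParams:
    """National-level (hyper) parameters of the region hierarchy.

    Transformed region parameters are exchangeable normal draws:
    d* ~ N(chi, psi²), Δ4* ~ N(Delta4_mean, delta4_sd²),
    γ_i ~ N(alpha_i, delta_sd_i²) for i = 1..3.
    """

    chi: float = 0.0
    psi: float = 0.5
    Delta4_mean: float = 0.0
    delta4_sd: float = 0.5
    alpha: tuple[float, float, float] = (0.0, 0.0, 0.0)
    delta_sd: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.psi <= 0 or self.delta4_sd <= 0 or any(d <= 0 for d in self.delta_sd):
            raise ParameterRangeError("hierarchy scale parameters must be > 0")


def double_logistic(theta: DeclineParams, f: float | np.ndarray) -> float | np.ndarray:
    """Expected five-year TFR decrement at level ``f``.

    Sum of two logistics with midpoints at Δ_4 + 0.5Δ_3 (the rise from 0
    to d_c just above the end-of-transition level) and ΣΔ − 0.5Δ_1 (the
    fall back to 0 just below the onset level); the decrement peaks
    mid-transition and vanishes at both extremes of the TFR range.
    """
    d1, _, d3, d4 = theta.delta
    if d1 == 0 or d3 == 0:
        raise ParameterRangeError("Delta_c1 and Delta_c3 must be > 0 (logistic slopes)")
    dc = theta.d_max
    U = theta.onset_level
    f = np.asarray(f, dtype=float) if isinstance(f, np.ndarray) else float(f)
    with np.errstate(over="ignore"):
        t1 = -dc / (1.0 + np.exp(-(_SLOPE / d1) * (f - U + 0.5 * d1)))
        t2 = dc / (1.0 + np.exp(-(_SLOPE / d3) * (f - d4 - 0.5 * d3)))
    return t1 + t2


def decrement(theta: DeclineParams, f: float | np.ndarray) -> float | np.ndarray:
    """Gated decrement d_{c,t}: the double logistic for f > 1, else 0."""
    g = double_logistic(theta, f)
    if isinstance(f, np.ndarray) or isinstance(g, np.ndarray):
        return np.where(np.asarray(f) > DECREMENT_GATE, g, 0.0)
    return g if f > DECREMENT_GATE else 0.0


def sigma_eps(
    f: float,
    t: int,
    dist: DistortionParams,
    grid: PeriodGrid,
    floor: float = SIGMA_FLOOR,
) -> float:
    """Distortion sd σ(f) for the step starting at period index ``t``.

    σ(f) = c(t)·(σ0 + (f−S)·(−a·1[f ≥ S] + b·1[f < S])), where
    c(t) = c1975 for periods starting 1970 or earlier and 1 afterwards
    (projection periods beyond the grid always use 1).  Clipped below at
    ``floor`` — 0.01 children by default, which keeps the likelihood
    proper; simulation callers pass 0 so that zero-noise configurations
    are exactly deterministic.
    """
    slope = -dist.a if f >= dist.S else dist.b
    base = dist.sigma0 + (f - dist.S) * slope
    c = dist.c1975 if grid.start_of(t) <= PRE1975_LAST_START else 1.0
    return max(c * base, floor)


def to_transformed(theta: DeclineParams) -> tuple[float, float, np.ndarray]:
    """Map θ_c to its unbounded hierarchy coordinates.

    Returns (d*, Δ4*, γ) with d* = logit-type map of d_c on (0.25, 2.5),
    Δ4* the analogous map of Δ_c4 on (1, 2.5), and γ the softmax
    coordinates of the shares p_i = Δ_ci/(U_c − Δ_c4), gauge-fixed so
    Σγ = 0.
    """
    d1, d2, d3, d4 = theta.delta
    dc = theta.d_max
    if not (D_LO < dc < D_HI):
        raise ParameterRangeError(f"d_c must lie in ({D_LO}, {D_HI}), got {dc}")
    if not (DELTA4_LO < d4 < DELTA4_HI):
        raise ParameterRangeError(f"Delta_c4 must lie in ({DELTA4_LO}, {DELTA4_HI}), got {d4}")
    if min(d1, d2, d3) <= 0:
        raise ParameterRangeError("Delta_c1..Delta_c3 must be > 0 for the softmax map")
    d_star = math.log((dc - D_LO) / (D_HI - dc))
    delta4_star = math.log((d4 - DELTA4_LO) / (DELTA4_HI - d4))
    rem = theta.onset_level - d4
    logp = np.log(np.array([d1, d2, d3]) / rem)
    gamma = logp - logp.mean()
    return d_star, delta4_star, gamma


def from_transformed(
    d_star: float,
    delta4_star: float,
    gamma: np.ndarray,
    U_c: float,
) -> DeclineParams:
    """Inverse of :func:`to_transformed`, given the onset level U_c."""
    dc = (D_LO + D_HI * math.exp(d_star)) / (1.0 + math.exp(d_star))
    d4 = (DELTA4_LO + DELTA4_HI * math.exp(delta4_star)) / (1.0 + math.exp(delta4_star))
    if U_c <= d4:
        raise ParameterRangeError(
            f"onset level U_c = {U_c} must exceed Delta_c4 = {d4:.4f}"
        )
    g = np.asarray(gamma, dtype=float)
    e = np.exp(g - g.max())
    p = e / e.sum()
    d123 = p * (U_c - d4)
    return DeclineParams(delta=(float(d123[0]), float(d123[1]), float(d123[2]), float(d4)), d_max=float(dc))
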