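"""Post-transition (Phase III) model: mean-reverting AR(1) around replacement.

Once a region has completed its fertility transition, the TFR oscillates
around (and recovers toward) the replacement level μ = 2.1 children per
woman:

    f_{t+1} ~ N(μ + ρ (f_t − μ), s²),    |ρ| < 1.

ρ and s are estimated by conditional maximum likelihood from the pooled
post-transition steps of all regions; μ is fixed, not estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ModelError, ParameterRangeError

#: Replacement-level long-run mean (children per woman).
REPLACEMENT_MU = 2.1

#: |rho| clip bound keeping the process stationary.
RHO_MAX = 0.999

#: Minimum number of (f_t, f_{t+1}) pairs for ML estimation.
MIN_PAIRS = 3


@dataclass(frozen=True)
class AR1Params:
    """Stationary AR(1) parameters: autocorrelation rho, innovation sd s,
    long-run mean mu (children per woman)."""

    rho: float
    s: float
    mu: float = REPLACEMENT_MU

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ParameterRangeError(f"|rho| must be < 1, got {self.rho}")
        if self.s < 0:
            raise ParameterRangeError(f"innovation sd must be >= 0, got {self.s}")

    @property
    def stationary_sd(self) -> float:
        return self.s / np.sqrt(1.0 - self.rho**2)


def fit_ar1_ml(pairs: np.ndarray, mu: float = REPLACEMENT_MU) -> AR1Params:
    """Conditional ML fit of the AR(1) from pooled (f_t, f_{t+1}) pairs.

    The conditional Gaussian likelihood Π N(f_{t+1}; μ + ρ(f_t − μ), s²)
    has the closed-form maximizer
    ρ̂ = Σ x_t y_t / Σ x_t² (with x = f_t − μ, y = f_{t+1} − μ) and
    ŝ² = mean squared residual.  ρ̂ is clipped into (−0.999, 0.999) with a
    warning if the raw estimate is non-stationary.

    Parameters
    ----------
    pairs : (n, 2) array of consecutive post-transition TFR observations,
        pooled across regions (pooling is order-free).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ModelError(f"pairs must be an (n, 2) array, got shape {pairs.shape}")
    n = pairs.shape[0]
    if n < MIN_PAIRS:
        raise ModelError(f"need >= {MIN_PAIRS} post-transition pairs, got {n}")
    x = pairs[:, 0] - mu
    y = pairs[:, 1] - mu
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ModelError("all f_t equal mu: rho is unidentifiable")
    rho = float(x @ y) / sxx
    if abs(rho) >= RHO_MAX:
        warnings.warn(
            f"raw AR(1) estimate rho = {rho:.4f} outside the stationary region; "
            f"clipped to +/-{RHO_MAX}",
            stacklevel=2,
        )
        rho = float(np.clip(rho, -RHO_MAX, RHO_MAX))
    resid = y - rho * x
    s = float(np.sqrt(np.mean(resid**2)))
    return AR1Params(rho=rho, s=s, mu=mu)


def ar1_step(
    f: float,
    params: AR1Params,
    noise: float,
    tfr_floor: float = 0.0,
) -> float:
    """One 5-year step: μ + ρ(f − μ) + s·noise, floored at ``tfr_floor``."""
    nxt = params.mu + params.rho * (f - params.mu) + params.s * noise
    return max(nxt, tfr_floor)


def collect_phase3_pairs(panel, assignments: dict) -> np.ndarray:
    """Pool consecutive Phase III (f_t, f_{t+1}) pairs across a panel.

    ``assignments`` maps region_id -> PhaseAssignment.  Only steps between
    consecutively observed post-transition periods are formed.
    """
    rows = []
    for s in panel.series:
        pa = assignments[s.region_id]
        for t in pa.phase3_step_indices():
            rows.append((s.values[t], s.values[t + 1]))
    return np.array(rows, dtype=float).reshape(-1, 2)
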