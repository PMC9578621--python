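"""Synthetic TFR panels with known ground truth.

The generator emulates the statistical structure of the three-phase model:
region parameters drawn from the hierarchy, a Phase I plateau just below
the onset peak, transition steps following the random walk with
double-logistic drift and level/era-dependent distortions, and a switch to
mean-reverting AR(1) dynamics once the region's transition completes (the
TFR first falls below its end-of-transition level Δ_c4).  The
post-transition pattern that detection looks for — two consecutive
increases with all three values below 2 children — then emerges from the
mean reversion itself, exactly as recoveries do in observed low-fertility
panels, and the recorded λ is the period where that pattern first holds on
the generated series, so deterministic detection recovers it exactly.

Ground-truth defaults are chosen so that transitions complete within a
1950–2020-style observation window: onset levels 6–7.5 children, maximum
pace d_c centred near 1.4 children per 5 years, low distortion noise.
These constants are this package's own choices for a plausible panel, not
estimates of any published series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ar1 import AR1Params
from .decline import (
    DeclineParams,
    DistortionParams,
    HierarchyParams,
    decrement,
    from_transformed,
    sigma_eps,
)
from .exceptions import ValidationError
from .periods import PeriodGrid, TFRPanel, TFRSeries
from .phases import LAMBDA_CEILING

#: Drop from the onset peak to the pre-transition plateau (children).
PLATEAU_DROP = 0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth configuration of a generated panel."""

    n_regions: int = 30
    grid: PeriodGrid = field(default_factory=lambda: PeriodGrid(1950, 14))
    hyper: HierarchyParams = field(
        default_factory=lambda: HierarchyParams(
            chi=0.3, psi=0.3, Delta4_mean=0.0, delta4_sd=0.3,
            alpha=(0.0, 0.0, 0.0), delta_sd=(0.3, 0.3, 0.3),
        )
    )
    dist: DistortionParams = field(
        default_factory=lambda: DistortionParams(
            m_tau=0.0, s_tau=0.1, sigma0=0.08, S=4.5, a=0.01, b=0.01, c1975=1.25,
        )
    )
    ar1: AR1Params = field(default_factory=lambda: AR1Params(rho=0.9, s=0.05))
    #: Period indices within which transition onsets are drawn.
    onset_window: tuple[int, int] = (0, 3)
    #: Uniform band of onset levels U_c (children per woman).
    onset_band: tuple[float, float] = (6.0, 7.5)
    tfr_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.onset_window
        if not (0 <= lo <= hi < len(self.grid)):
            raise ValidationError("onset_window must lie within the grid")
        if len(self.grid) - lo < 4:
            raise ValidationError("grid too short to contain a fertility transition")


@dataclass
class RegionTruth:
    """Recorded generative truth for one region."""

    theta: DeclineParams
    U: float
    tau: int
    lam: int | None        # None when the pattern never triggered in-window
    start_distortion: float
    #: First period simulated with post-transition AR(1) dynamics (the
    #: regime truth); the detectable λ pattern appears at or after it.
    regime_switch: int | None = None


@dataclass
class PanelTruth:
    spec: SyntheticSpec
    regions: dict[str, RegionTruth]

    def to_model_state(self):
        """The generating parameters as a ModelState (for projecting from
        known truth or seeding a sampler audit)."""
        from .decline import to_transformed
        from .mcmc import ModelState, RegionState

        regions = {}
        for rid, rt in self.regions.items():
            d_star, d4_star, gamma = to_transformed(rt.theta)
            regions[rid] = RegionState(
                d_star=d_star,
                delta4_star=d4_star,
                gamma=tuple(gamma),
                U=rt.U,
                U_sampled=False,
            )
        return ModelState(regions=regions, hyper=self.spec.hyper, dist=self.spec.dist)


def generate_panel(spec: SyntheticSpec) -> tuple[TFRPanel, PanelTruth]:
    """Generate a panel plus the full generative record.

    Per region: transformed parameters are drawn from the hierarchy,
    U_c uniformly in the onset band, and the onset period τ uniformly in
    the onset window.  Before τ the series sits on a plateau 0.25 children
    below the peak; at τ it peaks at U_c plus the start-period distortion;
    afterwards it follows the transition random walk until the
    post-transition pattern triggers, then AR(1).
    """
    rng = np.random.default_rng(spec.seed)
    h, d, grid = spec.hyper, spec.dist, spec.grid
    T = len(grid)
    series, truths = [], {}
    for r in range(spec.n_regions):
        rid = f"R{r + 1:02d}"
        d_star = rng.normal(h.chi, h.psi)
        d4_star = rng.normal(h.Delta4_mean, h.delta4_sd)
        gamma = rng.normal(np.array(h.alpha), np.array(h.delta_sd))
        U = rng.uniform(*spec.onset_band)
        tau = int(rng.integers(spec.onset_window[0], spec.onset_window[1] + 1))
        theta = from_transformed(d_star, d4_star, gamma, U)

        v = np.empty(T)
        v[:tau] = U - PLATEAU_DROP
        start_eps = float(rng.normal(d.m_tau, d.s_tau))
        v[tau] = U
        lam = None
        regime_switch = None
        in_ar1 = False
        for t in range(tau, T - 1):
            if in_ar1:
                nxt = spec.ar1.mu + spec.ar1.rho * (v[t] - spec.ar1.mu) + spec.ar1.s * rng.standard_normal()
            elif t == tau:
                nxt = v[t] - float(decrement(theta, float(v[t]))) + start_eps
            else:
                sd = sigma_eps(float(v[t]), t, d, grid, floor=0.0)
                nxt = v[t] - float(decrement(theta, float(v[t]))) + sd * rng.standard_normal()
            v[t + 1] = max(nxt, spec.tfr_floor)
            # regime truth: post-transition dynamics take over once the TFR
            # first falls below the region's end-of-transition level
            if not in_ar1 and v[t + 1] < theta.delta[3]:
                in_ar1 = True
                regime_switch = t + 1
            if (
                lam is None
                and t >= tau + 1
                and v[t + 1] > v[t] > v[t - 1]
                and v[t + 1] < LAMBDA_CEILING
                and v[t] < LAMBDA_CEILING
                and v[t - 1] < LAMBDA_CEILING
            ):
                lam = t  # pattern (f_{t-1}, f_t, f_{t+1}) centred at t
                in_ar1 = True
                if regime_switch is None:
                    regime_switch = t
        series.append(TFRSeries(rid, f"Synthetic region {r + 1}", v, grid))
        truths[rid] = RegionTruth(
            theta=theta, U=U, tau=tau, lam=lam,
            start_distortion=start_eps, regime_switch=regime_switch,
        )
    return TFRPanel(series), PanelTruth(spec=spec, regions=truths)


# hand-authored shape parameters of the packaged demo panel: per region
# (1950s level, decline onset year, minimum TFR, minimum year, recovery rise)
_FIXTURE_SHAPES = [
    ("R01", 2.85, 1975, 1.18, 1998, 0.22), ("R02", 3.10, 1972, 1.25, 1996, 0.18),
    ("R03", 2.60, 1978, 1.05, 2000, 0.15), ("R04", 2.95, 1974, 1.22, 1997, 0.20),
    ("R05", 3.30, 1970, 1.30, 1995, 0.24), ("R06", 2.70, 1977, 1.10, 1999, 0.00),
    ("R07", 2.90, 1975, 1.15, 1998, 0.19), ("R08", 3.05, 1973, 1.28, 1996, 0.21),
    ("R09", 2.55, 1979, 1.02, 2001, 0.12), ("R10", 3.20, 1971, 1.32, 1994, 0.25),
    ("R11", 2.80, 1976, 1.12, 1999, 0.00), ("R12", 2.98, 1974, 1.20, 1997, 0.17),
    ("R13", 3.15, 1972, 1.27, 1995, 0.23), ("R14", 2.65, 1978, 1.08, 2000, 0.14),
    ("R15", 2.88, 1975, 1.17, 1998, 0.20), ("R16", 3.00, 1973, 1.24, 1996, 0.00),
    ("R17", 2.75, 1977, 1.14, 1999, 0.16),
]


def spain_like_fixture() -> TFRPanel:
    """Packaged 18-series demo panel (17 regions + national aggregate).

    A synthetic stand-in qualitatively shaped like the Spanish experience —
    moderate-high 1950s TFR (~2.6–3.3 children), decline from the 1970s, a
    sub-replacement minimum in the late 1990s, then a mild recovery — built
    from smooth parametric curves.  The values are this package's own
    fixtures, not register or survey data.  Every regional peak stays below
    5.5 children, so all transitions predate the window (onset level enters
    the model as a parameter), and most regions trigger the
    post-transition pattern in the 2000s.
    """
    grid = PeriodGrid(1950, 14)  # 1950-1955 .. 2015-2020
    years = np.array([grid.start_of(t) for t in range(len(grid))], dtype=float)
    series = []
    acc = np.zeros(len(grid))
    for rid, level, onset, vmin, ymin, rise in _FIXTURE_SHAPES:
        half = (onset + ymin) / 2.0
        width = (ymin - onset) / 5.0
        drop = level - vmin
        v = vmin + drop / (1.0 + np.exp((years - half) / width))
        # mild recovery after the minimum, then a slight late decline
        post = np.clip((years - ymin) / 10.0, 0.0, 1.0)
        late = np.clip((years - 2010.0) / 10.0, 0.0, 1.0)
        v = v + rise * post - 0.4 * rise * late
        # deterministic small wiggle so the series is not perfectly smooth
        v = v + 0.015 * np.sin(0.9 * years % 6.28) * (v / 3.0)
        series.append(TFRSeries(rid, f"Demo region {rid[1:]}", np.round(v, 3), grid))
        acc += v
    national = np.round(acc / len(_FIXTURE_SHAPES), 3)
    series.append(TFRSeries("ES00", "Demo national aggregate", national, grid))
    return TFRPanel(series, national_id="ES00")
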