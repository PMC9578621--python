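"""Deterministic phase detection for regional TFR histories.

The fertility transition is segmented into three regimes:

* Phase I  — pre-transition high fertility plateau;
* Phase II — the transition: sustained decline from the onset period τ;
* Phase III — post-transition low fertility from the period λ, recognised
  once two consecutive increases are observed with all three TFR values
  below 2 children per woman.

The onset τ is the latest period that is a local maximum of the series,
lies within 0.5 children of the series maximum M, and exceeds 5.5 children
(a high-fertility start).  Series that never exceed 5.5 began their
transition before the observation window and get the sentinel
``BEFORE_OBSERVATION``; the whole observed history is then modelled as
Phase II (until λ, if reached).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import PhaseError
from .periods import TFRSeries

#: τ sentinel: the transition began before the first observed period.
BEFORE_OBSERVATION = "before_observation"
#: λ sentinel: the post-transition phase is not reached in the window.
NOT_REACHED = "not_reached"

#: Proximity to the series maximum required of the onset local peak (children).
TAU_PROXIMITY = 0.5
#: Minimum TFR of a qualifying onset peak (children per woman).
TAU_HIGH_FERTILITY = 5.5
#: Phase III is only recognised below this TFR (children per woman).
LAMBDA_CEILING = 2.0


class Phase(str, Enum):
    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True)
class PhaseAssignment:
    """Per-region phase segmentation: τ, λ and one label per period."""

    tau: int | str
    lam: int | str
    phase_per_period: tuple[Phase, ...]

    @property
    def tau_observed(self) -> bool:
        return isinstance(self.tau, int)

    @property
    def lam_observed(self) -> bool:
        return isinstance(self.lam, int)

    def phase2_step_indices(self, n_periods: int | None = None) -> list[int]:
        """Indices t such that the step t -> t+1 follows transition dynamics.

        Steps run from τ (or the first period, for pre-observation onsets)
        up to, not including, λ (or the last observed step).
        """
        n = len(self.phase_per_period) if n_periods is None else n_periods
        start = self.tau if self.tau_observed else 0
        stop = self.lam if self.lam_observed else n - 1
        return list(range(start, min(stop, n - 1)))

    def phase3_step_indices(self) -> list[int]:
        """Indices t of consecutive post-transition steps t -> t+1."""
        if not self.lam_observed:
            return []
        return list(range(self.lam, len(self.phase_per_period) - 1))


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices that are local maxima (ties count; endpoints one-sided)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    out = []
    for t in range(n):
        left_ok = t == 0 or v[t] >= v[t - 1]
        right_ok = t == n - 1 or v[t] >= v[t + 1]
        if left_ok and right_ok:
            out.append(t)
    return out


def detect_phase2_start(series: TFRSeries) -> int | str:
    """Transition onset τ, or ``BEFORE_OBSERVATION``.

    τ = max{t : t is a local maximum, M − f_t < 0.5, f_t > 5.5} with
    M = max_t f_t.  Regions whose peak never exceeds 5.5 children started
    declining before the window.
    """
    if len(series) < 3:
        raise PhaseError(
            f"region {series.region_id!r}: need >= 3 periods to locate local maxima"
        )
    v = series.values
    M = float(v.max())
    candidates = [
        t for t in _local_maxima(v)
        if (M - v[t]) < TAU_PROXIMITY and v[t] > TAU_HIGH_FERTILITY
    ]
    if not candidates:
        return BEFORE_OBSERVATION
    return max(candidates)


def detect_phase3_start(series: TFRSeries, tau: int | str) -> int | str:
    """Post-transition onset λ, or ``NOT_REACHED``.

    λ = min{t > τ : f_t > f_{t−1}, f_{t+1} > f_t, and f_p < 2 for
    p = t−1, t, t+1}.  Boundary periods cannot qualify because the rule
    references both neighbours.
    """
    v = series.values
    n = len(v)
    t0 = tau + 1 if isinstance(tau, int) else 1
    for t in range(max(t0, 1), n - 1):
        if (
            v[t] > v[t - 1]
            and v[t + 1] > v[t]
            and v[t - 1] < LAMBDA_CEILING
            and v[t] < LAMBDA_CEILING
            and v[t + 1] < LAMBDA_CEILING
        ):
            return t
    return NOT_REACHED


def assign_phases(series: TFRSeries) -> PhaseAssignment:
    """Segment a series into Phase I / II / III labels.

    Periods strictly before τ are Phase I (none when the onset predates the
    window), [τ, λ) are Phase II, and [λ, end] Phase III.
    """
    tau = detect_phase2_start(series)
    lam = detect_phase3_start(series, tau)
    n = len(series)
    start2 = tau if isinstance(tau, int) else 0
    start3 = lam if isinstance(lam, int) else n
    labels = tuple(
        Phase.I if t < start2 else (Phase.II if t < start3 else Phase.III)
        for t in range(n)
    )
    return PhaseAssignment(tau=tau, lam=lam, phase_per_period=labels)


def phase_table(panel) -> "pd.DataFrame":
    """Per-region summary table: τ, λ and phase step counts."""
    import pandas as pd

    rows = []
    for s in panel.series:
        pa = assign_phases(s)
        rows.append(
            {
                "region_id": s.region_id,
                "tau_period": s.grid.labels[pa.tau] if pa.tau_observed else "<" + s.grid.labels[0],
                "lambda_period": s.grid.labels[pa.lam] if pa.lam_observed else NOT_REACHED,
                "n_phase2_obs": len(pa.phase2_step_indices()),
                "n_phase3_obs": len(pa.phase3_step_indices()),
            }
        )
    return pd.DataFrame(rows)
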