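"""5-year period grids and TFR panel containers.

Demographic TFR estimates follow the UN convention of quinquennial periods
labelled "1950-1955", "1955-1960", ... A :class:`PeriodGrid` is the shared
time axis of a panel; internally periods are integer indices 0..T-1.  For
output tables a period is labelled by its mid-point year rounded down
(start year + 3), so the projection period "2020-2025" prints as 2023.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GridMismatchError, PeriodLabelError, TFRValueError

STEP = 5
_LABEL_RE = re.compile(r"^(\d{4})\s*[-–]\s*(\d{4})$")


def parse_period_label(label: str) -> int:
    """Return the start year of a 5-year period label such as '1950-1955'.

    Raises :class:`PeriodLabelError` for anything that is not a well-formed
    span of exactly five years.
    """
    m = _LABEL_RE.match(str(label).strip())
    if m is None:
        raise PeriodLabelError(f"malformed period label {label!r}; expected 'YYYY-YYYY'")
    start, end = int(m.group(1)), int(m.group(2))
    if end != start + STEP:
        raise PeriodLabelError(
            f"period label {label!r} does not span {STEP} years (got {end - start})"
        )
    return start


def period_label(start_year: int) -> str:
    return f"{start_year}-{start_year + STEP}"


@dataclass(frozen=True)
class PeriodGrid:
    """Contiguous, ordered 5-year period axis."""

    start_year: int
    n_periods: int

    def __post_init__(self) -> None:
        if self.n_periods < 1:
            raise PeriodLabelError("a period grid needs at least one period")

    @classmethod
    def from_labels(cls, labels: list[str]) -> "PeriodGrid":
        starts = [parse_period_label(lab) for lab in labels]
        if not starts:
            raise PeriodLabelError("empty period label list")
        for prev, cur in zip(starts, starts[1:]):
            if cur != prev + STEP:
                raise PeriodLabelError(
                    f"period labels not contiguous: {period_label(prev)!r} "
                    f"followed by {period_label(cur)!r}"
                )
        return cls(start_year=starts[0], n_periods=len(starts))

    @property
    def labels(self) -> list[str]:
        return [period_label(self.start_year + STEP * i) for i in range(self.n_periods)]

    def __len__(self) -> int:
        return self.n_periods

    def start_of(self, index: int) -> int:
        return self.start_year + STEP * index

    def mid_year(self, index: int) -> int:
        """Output-table year label for a period: start year + 3."""
        return self.start_of(index) + 3

    def index_of(self, label: str) -> int:
        start = parse_period_label(label)
        idx, rem = divmod(start - self.start_year, STEP)
        if rem != 0 or not 0 <= idx < self.n_periods:
            raise PeriodLabelError(f"period {label!r} not on grid {self.labels[0]}..{self.labels[-1]}")
        return idx

    def extended(self, horizon_end_year: int) -> "PeriodGrid":
        """Grid of future periods after this one, up to the period containing
        ``horizon_end_year`` (a period [y, y+5] contains its end year)."""
        first_future = self.start_of(self.n_periods)
        if horizon_end_year <= first_future:
            raise PeriodLabelError(
                f"horizon {horizon_end_year} does not extend past the last observed period"
            )
        n = (horizon_end_year - first_future + STEP - 1) // STEP
        return PeriodGrid(start_year=first_future, n_periods=n)


@dataclass
class TFRSeries:
    """One region's observed TFR history on a 5-year grid.

    ``values`` are total fertility rates in children per woman; all finite
    and strictly positive, one per grid period, no interior gaps.
    """

    region_id: str
    region_name: str
    values: np.ndarray
    grid: PeriodGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.grid):
            raise GridMismatchError(
                f"region {self.region_id!r}: {len(self.values)} values for "
                f"{len(self.grid)} periods"
            )
        bad = ~np.isfinite(self.values) | (self.values <= 0)
        if bad.any():
            i = int(np.argmax(bad))
            raise TFRValueError(
                f"region {self.region_id!r}, period {self.grid.labels[i]!r}: "
                f"TFR must be finite and > 0, got {self.values[i]!r}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TFRPanel:
    """Collection of TFR series sharing one period grid."""

    series: list[TFRSeries]
    national_id: str | None = None
    grid: PeriodGrid = field(init=False)

    def __post_init__(self) -> None:
        if not self.series:
            raise GridMismatchError("a panel needs at least one series")
        g0 = self.series[0].grid
        for s in self.series[1:]:
            if s.grid != g0:
                raise GridMismatchError(
                    f"region {s.region_id!r} grid {s.grid.labels[0]}..{s.grid.labels[-1]} "
                    f"differs from {g0.labels[0]}..{g0.labels[-1]}"
                )
        ids = [s.region_id for s in self.series]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GridMismatchError(f"duplicate region ids: {dup}")
        if self.national_id is not None and self.national_id not in ids:
            raise GridMismatchError(f"national id {self.national_id!r} not in panel")
        self.grid = g0

    def __len__(self) -> int:
        return len(self.series)

    def __getitem__(self, region_id: str) -> TFRSeries:
        for s in self.series:
            if s.region_id == region_id:
                return s
        raise KeyError(region_id)

    @property
    def region_ids(self) -> list[str]:
        return [s.region_id for s in self.series]
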