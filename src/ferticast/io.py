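"""CSV input/output for TFR panels and projection quantile tables.

Two panel dialects are supported:

* ``long`` — columns ``region_id,region_name,period,tfr``, one row per
  region-period;
* ``wide`` — one row per region with columns ``region_id,region_name``
  followed by one column per period label.

Values are kept at full double precision on round-trip; quantile tables are
rounded only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import TFRValueError, ValidationError
from .periods import PeriodGrid, TFRPanel, TFRSeries, parse_period_label, period_label

#: Quantile probabilities of the projection tables (fractions).
QUANTILE_PROBS = (0.025, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.975)

#: Serialized column header of a projection quantile table.
QUANTILE_HEADER = (
    "Year", "Mean", "SD",
    "2.5%", "5%", "10%", "25%", "50%", "75%", "90%", "95%", "97.5%",
)


@dataclass
class QuantileTable:
    """Per-year mean, sd and nine quantiles of simulated TFR trajectories."""

    years: np.ndarray          # (T,) int
    mean: np.ndarray           # (T,)
    sd: np.ndarray             # (T,)
    quantiles: np.ndarray      # (T, 9) columns ordered by QUANTILE_PROBS

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        T = len(self.years)
        if self.mean.shape != (T,) or self.sd.shape != (T,) or self.quantiles.shape != (T, len(QUANTILE_PROBS)):
            raise ValidationError("quantile table shapes inconsistent")
        if (self.sd < 0).any():
            raise ValidationError("negative SD in quantile table")
        if (np.diff(self.quantiles, axis=1) < -1e-12).any():
            raise ValidationError("quantile columns not non-decreasing in probability")

    @property
    def median(self) -> np.ndarray:
        return self.quantiles[:, QUANTILE_PROBS.index(0.50)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"Year": self.years, "Mean": self.mean, "SD": self.sd})
        for j, p in enumerate(QUANTILE_PROBS):
            df[QUANTILE_HEADER[3 + j]] = self.quantiles[:, j]
        return df


def read_tfr_panel(path: str | Path, dialect: str = "long") -> TFRPanel:
    """Read a TFR panel CSV in the ``long`` or ``wide`` dialect.

    Every series is validated (positive finite TFR, shared contiguous grid);
    period labels are normalized to ``YYYY-YYYY``.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(
            path,
            dtype={"region_id": str, "region_name": str, "period": str},
            float_precision="round_trip",
        )
        required = {"region_id", "region_name", "period", "tfr"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"long panel {path} missing columns {sorted(missing)}")
        series = []
        for rid, grp in df.groupby("region_id", sort=False):
            labels = [period_label(parse_period_label(p)) for p in grp["period"]]
            order = np.argsort([parse_period_label(p) for p in labels])
            grp = grp.iloc[order]
            labels = [labels[i] for i in order]
            vals = pd.to_numeric(grp["tfr"], errors="coerce").to_numpy()
            _check_values(rid, labels, vals)
            grid = PeriodGrid.from_labels(labels)
            series.append(TFRSeries(str(rid), str(grp["region_name"].iloc[0]), vals, grid))
        return TFRPanel(series)
    if dialect == "wide":
        df = pd.read_csv(
            path,
            dtype={"region_id": str, "region_name": str},
            float_precision="round_trip",
        )
        period_cols = [c for c in df.columns if c not in ("region_id", "region_name")]
        labels = [period_label(parse_period_label(c)) for c in period_cols]
        grid = PeriodGrid.from_labels(labels)
        series = []
        for _, row in df.iterrows():
            vals = pd.to_numeric(row[period_cols], errors="coerce").to_numpy()
            _check_values(row["region_id"], labels, vals)
            series.append(TFRSeries(str(row["region_id"]), str(row["region_name"]), vals, grid))
        return TFRPanel(series)
    raise ValidationError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def _check_values(region_id: str, labels: list[str], vals: np.ndarray) -> None:
    for lab, v in zip(labels, vals):
        if not np.isfinite(v):
            raise TFRValueError(f"region {region_id!r}, period {lab!r}: non-numeric TFR")
        if v <= 0:
            raise TFRValueError(f"region {region_id!r}, period {lab!r}: non-positive TFR {v}")


def write_tfr_panel(panel: TFRPanel, path: str | Path, dialect: str = "long") -> None:
    """Write a panel so that :func:`read_tfr_panel` round-trips it exactly."""
    if not isinstance(panel, TFRPanel) or len(panel) == 0:
        raise ValidationError("refusing to write an empty or invalid panel")
    path = Path(path)
    labels = panel.grid.labels
    if dialect == "long":
        rows = [
            {"region_id": s.region_id, "region_name": s.region_name, "period": lab, "tfr": v}
            for s in panel.series
            for lab, v in zip(labels, s.values)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "wide":
        rows = []
        for s in panel.series:
            row: dict = {"region_id": s.region_id, "region_name": s.region_name}
            row.update(dict(zip(labels, s.values)))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def write_quantile_table(qt: QuantileTable, path: str | Path) -> None:
    """Write a projection table with the canonical 12-column header.

    Rows are emitted in ascending year order; TFR columns are rounded to
    2 decimals and the SD column to 3 at serialization only.
    """
    if not isinstance(qt, QuantileTable):
        raise ValidationError("expected a QuantileTable")
    df = qt.to_frame().sort_values("Year")
    out = pd.DataFrame({"Year": df["Year"].astype(int)})
    out["Mean"] = df["Mean"].round(2)
    out["SD"] = df["SD"].round(3)
    for c in QUANTILE_HEADER[3:]:
        out[c] = df[c].round(2)
    out.to_csv(path, index=False)


def read_quantile_table(path: str | Path) -> QuantileTable:
    df = pd.read_csv(path)
    if tuple(df.columns) != QUANTILE_HEADER:
        raise ValidationError(f"unexpected quantile table header in {path}")
    q = df[list(QUANTILE_HEADER[3:])].to_numpy()
    return QuantileTable(df["Year"].to_numpy(), df["Mean"].to_numpy(), df["SD"].to_numpy(), q)


def make_quantile_table(years, trajectories: np.ndarray) -> QuantileTable:
    """Summarize a (n_trajectories, T) matrix into a QuantileTable."""
    traj = np.asarray(trajectories, dtype=float)
    mean = traj.mean(axis=0)
    sd = traj.std(axis=0, ddof=1) if traj.shape[0] > 1 else np.zeros(traj.shape[1])
    q = np.quantile(traj, QUANTILE_PROBS, axis=0).T
    return QuantileTable(np.asarray(years), mean, sd, q)
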