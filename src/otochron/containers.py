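"""Core data containers: monthly climate series, annual stock series, and the
increment (growth) table that the models are fitted on.

All three are thin, validated wrappers around pandas DataFrames with CSV
round-tripping; the heavy lifting happens in the analysis modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ClimateSeries", "StockSeries", "GrowthTable"]


@dataclass
class ClimateSeries:
    """Monthly climate values (one value per calendar month, no gaps).

    ``data`` has columns ``year``, ``month`` (1-12) and ``value`` (degC).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data[["year", "month", "value"]].copy()
        df = df.sort_values(["year", "month"]).reset_index(drop=True)
        t = df["year"].to_numpy() * 12 + df["month"].to_numpy() - 1
        if len(t) == 0:
            raise DataError("empty climate series")
        if df["month"].min() < 1 or df["month"].max() > 12:
            raise DataError("climate months must be in 1..12")
        dt = np.diff(t)
        if np.any(dt == 0):
            raise DataError("duplicate climate months")
        if np.any(dt != 1):
            raise DataError("climate series has month gaps")
        self.data = df
        # fast lookup: absolute month index -> value
        self._t0 = int(t[0])
        self._values = df["value"].to_numpy()

    @property
    def start(self) -> tuple[int, int]:
        return int(self.data["year"].iloc[0]), int(self.data["month"].iloc[0])

    @property
    def end(self) -> tuple[int, int]:
        return int(self.data["year"].iloc[-1]), int(self.data["month"].iloc[-1])

    def values_at(self, tindex: np.ndarray) -> np.ndarray:
        """Values at absolute month indices (year*12 + month - 1).

        Returns NaN where the series has no coverage.
        """
        tindex = np.asarray(tindex)
        idx = tindex - self._t0
        ok = (idx >= 0) & (idx < len(self._values))
        out = np.full(tindex.shape, np.nan)
        out[ok] = self._values[idx[ok]]
        return out

    def value(self, year: int, month: int) -> float:
        v = self.values_at(np.array([year * 12 + month - 1]))[0]
        if np.isnan(v):
            raise DataError(f"no climate value for {year}-{month:02d}")
        return float(v)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClimateSeries":
        return cls(pd.read_csv(path))


@dataclass
class StockSeries:
    """Annual stock covariates: an abundance index per (year, age) and a
    harvest rate per year.

    ``n_index`` has columns ``year``, ``age``, ``n_index`` (within-age z-score
    of log abundance); ``hr`` has columns ``year``, ``hr`` with hr in [0, 1].
    """

    n_index: pd.DataFrame
    hr: pd.DataFrame

    def __post_init__(self) -> None:
        self.n_index = self.n_index[["year", "age", "n_index"]].reset_index(drop=True)
        self.hr = self.hr[["year", "hr"]].reset_index(drop=True)
        if ((self.hr["hr"] < 0) | (self.hr["hr"] > 1)).any():
            raise DataError("harvest rate must lie in [0, 1]")
        if self.n_index.duplicated(["year", "age"]).any():
            raise DataError("duplicate (year, age) in abundance index")

    def to_csv(self, n_path: str | Path, hr_path: str | Path) -> None:
        self.n_index.to_csv(n_path, index=False)
        self.hr.to_csv(hr_path, index=False)

    @classmethod
    def from_csv(cls, n_path: str | Path, hr_path: str | Path) -> "StockSeries":
        return cls(pd.read_csv(n_path), pd.read_csv(hr_path))


@dataclass
class GrowthTable:
    """The modelling frame: one row per fish x increment age.

    ``data`` always carries ``fish_id``, ``cohort``, ``year``, ``age`` and
    ``width_um``; filtering, covariate attachment and transformation add
    columns in place of producing new containers.  ``centering`` maps each
    centered column to the constant that was subtracted, so fitted models can
    reproduce their design on new data.
    """

    data: pd.DataFrame
    centering: dict = field(default_factory=dict)
    filtered: bool = False
    filter_report: dict | None = None

    def __post_init__(self) -> None:
        required = {"fish_id", "age", "width_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"growth table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "GrowthTable":
        return GrowthTable(
            self.data.copy(),
            centering=dict(self.centering),
            filtered=self.filtered,
            filter_report=None if self.filter_report is None else dict(self.filter_report),
        )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "GrowthTable":
        return cls(pd.read_csv(path), **kwargs)
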