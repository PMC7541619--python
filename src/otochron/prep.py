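"""Raw increment tables -> modelling frame.

Filtering follows the measurement protocol for annual otolith increments:
the first increment and the last (edge, incompletely formed) increment of
each fish are excluded, as are the rare increments formed after the 10th
year of life.  Widths are log-transformed and ln(age) plus every continuous
covariate are mean-centered, with the constants recorded so a fitted model
can reproduce its design on new data.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ClimateSeries, GrowthTable, StockSeries
from .errors import CoverageError, DataError, ParameterError
from .windows import WindowDef, _window_values

__all__ = [
    "apply_filters",
    "transform",
    "build_n_index",
    "attach_covariates",
]

#: continuous covariates that `transform` centers when present
CENTERED_COVARIATES = ("sst", "n_index", "hr", "sst_among")


def apply_filters(raw, *, age_cap: int = 10) -> GrowthTable:
    """Drop per-fish edge increments (minimum and maximum recorded age), then
    increments formed after ``age_cap``; fish left with no rows are counted
    as a warning, not an error.  Idempotent: an already-filtered table is
    returned unchanged.
    """
    if isinstance(raw, GrowthTable):
        if raw.filtered:
            return raw
        df = raw.data
    else:
        df = raw
    report = {"rows_in": int(len(df)), "removed_edge": 0, "removed_age_cap": 0,
              "rows_out": 0, "fish_in": 0, "fish_out": 0, "fish_empty": 0}
    if len(df) == 0:
        out = df.copy()
        return GrowthTable(_ensure_year_cohort(out, allow_empty=True),
                           filtered=True, filter_report=report)
    if (df["width_um"] <= 0).any():
        bad = int((df["width_um"] <= 0).sum())
        raise DataError(f"{bad} rows with non-positive increment width")
    df = _ensure_year_cohort(df.copy())
    report["fish_in"] = int(df["fish_id"].nunique())

    ages = df.groupby("fish_id")["age"]
    amin, amax, cnt = ages.transform("min"), ages.transform("max"), ages.transform("size")
    span = df.groupby("fish_id")["age"].agg(lambda a: a.max() - a.min() + 1 == len(a))
    if not span.all():
        bad = span.index[~span].tolist()
        raise DataError(f"non-contiguous increment ages for fish: {bad[:5]}")

    edge = (df["age"] == amin) | (df["age"] == amax)
    report["removed_edge"] = int(edge.sum())
    kept = df[~edge]
    cap = kept["age"] > age_cap
    report["removed_age_cap"] = int(cap.sum())
    kept = kept[~cap]
    report["rows_out"] = int(len(kept))
    report["fish_out"] = int(kept["fish_id"].nunique())
    report["fish_empty"] = report["fish_in"] - report["fish_out"]
    return GrowthTable(kept.reset_index(drop=True), filtered=True,
                       filter_report=report)


def _ensure_year_cohort(df: pd.DataFrame, allow_empty: bool = False) -> pd.DataFrame:
    if "cohort" not in df.columns:
        if {"catch_year", "age_at_catch"} <= set(df.columns):
            df["cohort"] = df["catch_year"] - df["age_at_catch"]
        elif not allow_empty:
            raise DataError("need 'cohort' or ('catch_year', 'age_at_catch') columns")
        else:
            df["cohort"] = pd.Series(dtype=int)
    if "year" not in df.columns:
        df["year"] = df["cohort"] + df["age"]
    bad = df["year"] != df["cohort"] + df["age"]
    if bad.any():
        raise DataError(f"{int(bad.sum())} rows violate year = cohort + age")
    return df


def transform(table: GrowthTable, centering: dict | None = None) -> GrowthTable:
    """Add ``log_width`` and centered ``log_age_c`` plus a centered ``*_c``
    column for every continuous covariate present; record the constants.

    With ``centering`` given, those constants are reused instead of
    re-estimated (required to score new data with a fitted model)."""
    out = table.copy()
    df = out.data
    if (df["width_um"] <= 0).any():
        raise DataError("non-positive widths cannot be log-transformed")
    df["log_width"] = np.log(df["width_um"].to_numpy(dtype=float))
    needed = ["log_age"] + [c for c in CENTERED_COVARIATES if c in df.columns]
    if centering is not None:
        missing = [c for c in needed if c not in centering]
        if missing:
            raise ParameterError(f"fixed centering constants missing for: {missing}")
        consts = {c: float(centering[c]) for c in needed}
    else:
        consts = {}
        consts["log_age"] = float(np.log(df["age"].to_numpy(dtype=float)).mean())
        for c in needed[1:]:
            consts[c] = float(df[c].mean())
    df["log_age_c"] = np.log(df["age"].to_numpy(dtype=float)) - consts["log_age"]
    for c in needed[1:]:
        df[f"{c}_c"] = df[c] - consts[c]
    out.centering.update(consts)
    return out


def build_n_index(abundance: pd.DataFrame) -> pd.DataFrame:
    """Abundance-at-age by year -> density index: within each age class the
    z-score (sample sd) of log abundance across years."""
    df = abundance[["year", "age", "abundance"]].copy()
    if (df["abundance"] <= 0).any():
        raise DataError("abundances must be strictly positive")
    df["log_n"] = np.log(df["abundance"])
    out = []
    for age, grp in df.groupby("age"):
        if len(grp) < 2:
            raise DataError(f"age class {age} has a single year; z-score undefined")
        sd = grp["log_n"].std(ddof=1)
        if sd == 0:
            raise DataError(f"age class {age} has constant abundance; z-score undefined")
        z = (grp["log_n"] - grp["log_n"].mean()) / sd
        out.append(pd.DataFrame({"year": grp["year"], "age": age, "n_index": z}))
    return pd.concat(out).sort_values(["age", "year"]).reset_index(drop=True)


def attach_covariates(table: GrowthTable, climate: ClimateSeries | None = None,
                      window: WindowDef | None = None,
                      stock: StockSeries | None = None,
                      sst_name: str = "sst") -> GrowthTable:
    """Attach the windowed climate aggregate (per formation year), the
    density index at (year, age), and the harvest rate at year."""
    out = table.copy()
    df = out.data
    years = df["year"].to_numpy(dtype=np.int64)
    if climate is not None:
        if window is None:
            raise ParameterError("climate given without a window")
        df[sst_name] = _window_values(climate, window, years)
    if stock is not None:
        nidx = stock.n_index.set_index(["year", "age"])["n_index"]
        keys = pd.MultiIndex.from_arrays([df["year"], df["age"]])
        vals = nidx.reindex(keys)
        if vals.isna().any():
            miss = sorted(set(keys[vals.isna().to_numpy()]))
            raise CoverageError(
                f"abundance index missing for (year, age): {miss[:5]}", missing=miss)
        df["n_index"] = vals.to_numpy()
        hr = stock.hr.set_index("year")["hr"].reindex(df["year"])
        if hr.isna().any():
            miss = sorted(set(df["year"][hr.isna().to_numpy()]))
            raise CoverageError(f"harvest rate missing for years: {miss[:5]}",
                                missing=miss)
        df["hr"] = hr.to_numpy()
    return out
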