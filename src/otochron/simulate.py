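"""Synthetic otolith-increment data with known truth.

The generator runs the extended growth model forward: log increment width is
an age-dependent decline plus crossed random effects (fish, formation year,
cohort, each with a correlated random age slope), a within-individual and an
among-individual temperature effect, an individual (fish-level) random
thermal slope whose variance may differ between cohorts, density-dependence
terms, and i.i.d. Gaussian residual noise.  Defaults put every parameter on
the scale of the Icelandic-cod estimates so that downstream recovery tests
run under realistic signal-to-noise.

Everything is reproducible: all draws come from one seeded generator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .containers import ClimateSeries, GrowthTable, StockSeries
from .errors import CoverageError, DataError, ParameterError
from .prep import build_n_index
from .windows import WindowDef, _window_values

__all__ = [
    "DEFAULT_SEED",
    "SimulationTruth",
    "simulate_climate",
    "simulate_population",
    "simulate_stock",
    "simulate_increments",
    "cohort_env_means",
    "linear_slope_variance",
]

DEFAULT_SEED = 20141007


@dataclass
class SimulationTruth:
    """Generating parameters of the extended growth model.

    Units: the response is ln(increment width in um); temperature slopes are
    per degC; ``var_slope_fish`` may be a single variance or a mapping
    cohort -> variance (heterogeneous individual plasticity).
    """

    alpha0: float = 5.326          # ln-um growth at centered age, average env
    beta_age: float = -0.645       # decline per unit centered ln(age)
    beta_w: float = 0.020          # within-individual temperature slope
    beta_a: float = 0.069          # among-individual temperature slope
    beta_age_w: float = -0.092     # age x within-temperature interaction
    beta_n: float = -0.002         # abundance main effect
    beta_age_n: float = 0.017      # age x abundance interaction
    var_fish: float = 0.007
    var_year: float = 0.002
    var_cohort: float = 0.001
    var_age_fish: float = 0.012
    var_age_year: float = 0.001
    var_age_cohort: float = 0.004
    rho_fish: float = 0.440
    rho_year: float = -0.107
    rho_cohort: float = 0.167
    var_slope_fish: float | Mapping[int, float] = 0.005
    sigma2: float = 0.056
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        for name in ("var_fish", "var_year", "var_cohort", "var_age_fish",
                     "var_age_year", "var_age_cohort", "sigma2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("rho_fish", "rho_year", "rho_cohort"):
            if abs(getattr(self, name)) > 1:
                raise ParameterError(f"{name} must lie in [-1, 1]")
        if isinstance(self.var_slope_fish, Mapping):
            if any(v < 0 for v in self.var_slope_fish.values()):
                raise ParameterError("cohort slope variances must be >= 0")
        elif self.var_slope_fish < 0:
            raise ParameterError("var_slope_fish must be >= 0")

    def slope_variance(self, cohorts: np.ndarray) -> np.ndarray:
        if isinstance(self.var_slope_fish, Mapping):
            missing = sorted(set(cohorts.tolist()) - set(self.var_slope_fish))
            if missing:
                raise ParameterError(
                    f"var_slope_fish mapping lacks cohorts: {missing[:5]}")
            return np.array([self.var_slope_fish[c] for c in cohorts], dtype=float)
        return np.full(len(cohorts), float(self.var_slope_fish))

    def to_json(self, path) -> None:
        d = self.__dict__.copy()
        if isinstance(d["var_slope_fish"], Mapping):
            d["var_slope_fish"] = {str(k): float(v)
                                   for k, v in d["var_slope_fish"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def simulate_climate(start_year: int, end_year: int, *, mean: float = 7.0,
                     amplitude: float = 3.0, ar_coef: float = 0.6,
                     sd: float = 0.5, seed: int = DEFAULT_SEED,
                     month_sd: float | None = None) -> ClimateSeries:
    """Monthly climate: sinusoidal seasonal cycle (peak in August) plus a
    stationary AR(1) annual anomaly (innovation sd ``sd``) plus independent
    monthly noise (``month_sd``, default sd/2 so that single months remain
    distinguishable within a year; zero whenever ``sd`` is zero)."""
    if start_year > end_year:
        raise ParameterError("start_year must be <= end_year")
    if sd < 0:
        raise ParameterError("sd must be >= 0")
    if abs(ar_coef) >= 1:
        raise ParameterError("|ar_coef| must be < 1")
    if month_sd is None:
        month_sd = sd / 2.0
    if month_sd < 0:
        raise ParameterError("month_sd must be >= 0")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    anom = np.zeros(len(years))
    if sd > 0:
        anom[0] = rng.normal(0.0, sd / np.sqrt(1 - ar_coef ** 2))
        for i in range(1, len(years)):
            anom[i] = ar_coef * anom[i - 1] + rng.normal(0.0, sd)
    months = np.arange(1, 13)
    seasonal = mean + amplitude * np.cos(2 * np.pi * (months - 8) / 12.0)
    rows = {
        "year": np.repeat(years, 12),
        "month": np.tile(months, len(years)),
        "value": (np.repeat(anom, 12) + np.tile(seasonal, len(years))
                  + (rng.normal(0.0, month_sd, 12 * len(years))
                     if month_sd > 0 else 0.0)),
    }
    return ClimateSeries(pd.DataFrame(rows))


def simulate_population(n_fish: int, catch_years, *,
                        age_at_catch_range: tuple[int, int] = (8, 12),
                        seed: int = DEFAULT_SEED,
                        sex_ratio: float = 0.5) -> pd.DataFrame:
    """Fish roster: catch year, age at catch, cohort (= catch year - age at
    catch) and sex, emulating archive sampling of mature fish."""
    if n_fish <= 0:
        raise ParameterError("n_fish must be > 0")
    catch_years = np.asarray(list(catch_years), dtype=int)
    if len(catch_years) == 0:
        raise ParameterError("catch_years is empty")
    lo, hi = age_at_catch_range
    if not (3 <= lo <= hi):
        raise ParameterError("age_at_catch_range must satisfy 3 <= lo <= hi")
    rng = np.random.default_rng(seed)
    catch = rng.choice(catch_years, n_fish)
    age = rng.integers(lo, hi + 1, n_fish)
    sex = np.where(rng.random(n_fish) < sex_ratio, "F", "M")
    return pd.DataFrame({
        "fish_id": np.arange(n_fish),
        "catch_year": catch,
        "age_at_catch": age,
        "cohort": catch - age,
        "sex": sex,
    })


def simulate_stock(years, ages=range(2, 11), *, seed: int = DEFAULT_SEED,
                   ar_coef: float = 0.7, sd: float = 0.4,
                   hr_mean: float = 0.25, hr_sd: float = 0.08) -> StockSeries:
    """Annual stock series: AR(1) log-abundance per age class (turned into
    the within-age z-score index) and a smoothly varying harvest rate."""
    rng = np.random.default_rng(seed)
    years = np.asarray(list(years), dtype=int)
    ages = np.asarray(list(ages), dtype=int)
    rows = []
    for a in ages:
        logn = np.zeros(len(years))
        logn[0] = rng.normal(0, sd / np.sqrt(1 - ar_coef ** 2))
        for i in range(1, len(years)):
            logn[i] = ar_coef * logn[i - 1] + rng.normal(0, sd)
        base = 12.0 - 0.5 * (a - ages[0])  # older age groups are rarer
        rows.append(pd.DataFrame({"year": years, "age": a,
                                  "abundance": np.exp(base + logn)}))
    n_index = build_n_index(pd.concat(rows, ignore_index=True))
    h = np.zeros(len(years))
    h[0] = rng.normal(0, hr_sd / np.sqrt(1 - ar_coef ** 2))
    for i in range(1, len(years)):
        h[i] = ar_coef * h[i - 1] + rng.normal(0, hr_sd)
    hr = np.clip(hr_mean + h, 0.01, 0.9)
    return StockSeries(n_index=n_index, hr=pd.DataFrame({"year": years, "hr": hr}))


def _cov_factor(var0, var1, rho):
    c01 = rho * np.sqrt(var0 * var1)
    cov = np.array([[var0, c01], [c01, var1]])
    w, U = np.linalg.eigh(cov)  # PSD factor exact for zero variances
    if w.min() < -1e-12:
        raise ParameterError("random-effect covariance not positive semidefinite")
    return U * np.sqrt(np.clip(w, 0.0, None))


def _level_normals(seed: int, tag: int, levels, per_level: int) -> np.ndarray:
    """Standard normals keyed by (seed, tag, level value): the draw for a
    given fish/year/cohort does not depend on which other levels are present,
    so enlarging the roster reuses the same year and cohort effects."""
    out = np.empty((len(levels), per_level))
    for i, lv in enumerate(levels):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(tag, int(lv))))
        out[i] = rng.standard_normal(per_level)
    return out


def simulate_increments(truth: SimulationTruth, roster: pd.DataFrame,
                        climate: ClimateSeries, stock: StockSeries | None = None,
                        *, window: WindowDef = WindowDef(8, 8),
                        support: str = "filtered",
                        age_cap: int = 10) -> tuple[GrowthTable, dict]:
    """Run the extended growth model generatively.

    ``support='filtered'`` emits ages 2..min(age_at_catch-1, age_cap) per
    fish (the retained support after edge/age filtering); ``'raw'`` emits
    1..age_at_catch so the filtering stage itself can be exercised.  Returns
    the growth table and a truth record (per-row linear predictor, the drawn
    random effects, and the design constants used)."""
    if support not in ("filtered", "raw"):
        raise ParameterError("support must be 'filtered' or 'raw'")
    rng = np.random.default_rng(truth.seed)
    fish_ids = roster["fish_id"].to_numpy()
    n_fish = len(fish_ids)

    rows = []
    for fid, catch_age, cohort, sex in zip(
            fish_ids, roster["age_at_catch"], roster["cohort"], roster["sex"]):
        if support == "filtered":
            ages = np.arange(2, min(int(catch_age), age_cap + 1))
        else:
            ages = np.arange(1, int(catch_age) + 1)
        if len(ages) == 0:
            continue
        rows.append(pd.DataFrame({
            "fish_id": fid, "cohort": int(cohort), "age": ages,
            "year": int(cohort) + ages, "sex": sex,
        }))
    df = pd.concat(rows, ignore_index=True)
    n = len(df)

    # retained mask defines the support on which the lifetime mean and the
    # centering constants are computed, regardless of emitted support
    retained = (df["age"] >= 2) & (df["age"] <= np.minimum(
        df["fish_id"].map(roster.set_index("fish_id")["age_at_catch"]) - 1, age_cap))
    years = df["year"].to_numpy()
    try:
        sst = _window_values(climate, window, years)
    except CoverageError as e:
        raise CoverageError(
            f"climate does not cover the simulated life spans: {e}",
            missing=e.missing) from e

    sst_s = pd.Series(sst, index=df.index)
    xbar_fish = sst_s[retained].groupby(df.loc[retained, "fish_id"]).mean()
    if not xbar_fish.index.equals(pd.Index(sorted(df["fish_id"].unique()))):
        xbar_fish = xbar_fish.reindex(sorted(df["fish_id"].unique()))
        if xbar_fish.isna().any():
            raise DataError("some fish have no retained increments")
    xbar = df["fish_id"].map(xbar_fish).to_numpy()
    within = sst - xbar
    c_among = float(pd.Series(xbar)[retained].mean())
    among_c = xbar - c_among
    log_age = np.log(df["age"].to_numpy(dtype=float))
    c_age = float(log_age[retained.to_numpy()].mean())
    x_age = log_age - c_age

    if stock is not None:
        nidx = stock.n_index.set_index(["year", "age"])["n_index"]
        keys = pd.MultiIndex.from_arrays([df["year"], df["age"]])
        nvals = nidx.reindex(keys)
        if nvals.isna().any():
            miss = sorted(set(keys[nvals.isna().to_numpy()]))
            raise CoverageError(f"stock index missing (year, age): {miss[:5]}",
                                missing=miss)
        nvals = nvals.to_numpy()
    else:
        nvals = np.zeros(n)

    # random effects, keyed per level so draws are stable across rosters
    fish_codes, fish_levels = pd.factorize(df["fish_id"], sort=True)
    year_codes, year_levels = pd.factorize(df["year"], sort=True)
    coh_codes, coh_levels = pd.factorize(df["cohort"], sort=True)
    zf = _level_normals(truth.seed, 1, fish_levels, 3)
    bf = zf[:, :2] @ _cov_factor(truth.var_fish, truth.var_age_fish,
                                 truth.rho_fish).T
    by = _level_normals(truth.seed, 2, year_levels, 2) @ _cov_factor(
        truth.var_year, truth.var_age_year, truth.rho_year).T
    bc = _level_normals(truth.seed, 3, coh_levels, 2) @ _cov_factor(
        truth.var_cohort, truth.var_age_cohort, truth.rho_cohort).T
    fish_cohort = roster.set_index("fish_id")["cohort"].reindex(fish_levels).to_numpy()
    sv = truth.slope_variance(fish_cohort)
    bw = zf[:, 2] * np.sqrt(sv)

    linpred = (truth.alpha0
               + truth.beta_age * x_age
               + truth.beta_w * within + truth.beta_a * among_c
               + truth.beta_age_w * x_age * within
               + truth.beta_n * nvals + truth.beta_age_n * x_age * nvals
               + bf[fish_codes, 0] + bf[fish_codes, 1] * x_age
               + bw[fish_codes] * within
               + by[year_codes, 0] + by[year_codes, 1] * x_age
               + bc[coh_codes, 0] + bc[coh_codes, 1] * x_age)
    eps = (rng.standard_normal(n) * np.sqrt(truth.sigma2)
           if truth.sigma2 > 0 else np.zeros(n))
    df["width_um"] = np.exp(linpred + eps)

    table = GrowthTable(df[["fish_id", "cohort", "year", "age", "width_um",
                            "sex"]].copy(),
                        filtered=(support == "filtered"))
    info = {
        "linpred": linpred,
        "c_age": c_age,
        "c_among": c_among,
        "window": window,
        "fish_effects": pd.DataFrame({
            "fish_id": fish_levels, "intercept": bf[:, 0],
            "age_slope": bf[:, 1], "within_slope": bw,
            "slope_variance": sv, "xbar": xbar_fish.to_numpy()}),
        "year_effects": pd.DataFrame({
            "year": year_levels, "intercept": by[:, 0], "age_slope": by[:, 1]}),
        "cohort_effects": pd.DataFrame({
            "cohort": coh_levels, "intercept": bc[:, 0], "age_slope": bc[:, 1]}),
    }
    return table, info


def cohort_env_means(roster: pd.DataFrame, climate: ClimateSeries,
                     window: WindowDef = WindowDef(8, 8),
                     age_cap: int = 10) -> pd.Series:
    """Mean windowed climate each cohort experiences over its retained
    increment years (used to build cohort-dependent plasticity variance)."""
    out = {}
    for cohort, grp in roster.groupby("cohort"):
        ages = np.arange(2, min(int(grp["age_at_catch"].max()), age_cap + 1))
        yrs = int(cohort) + ages
        out[int(cohort)] = float(np.mean(_window_values(climate, window, yrs)))
    return pd.Series(out).sort_index()


def linear_slope_variance(cohort_env: pd.Series, base: float,
                          gradient: float, floor: float = 1e-4) -> dict[int, float]:
    """Cohort -> slope variance with a linear dependence on the cohort-mean
    environment (centered), clipped below at ``floor``."""
    centered = cohort_env - cohort_env.mean()
    return {int(c): float(max(base + gradient * v, floor))
            for c, v in centered.items()}
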