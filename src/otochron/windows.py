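"""Sliding-window selection of the climate signal.

Candidate windows are month spans counted back from December of the growth
year (0..23 months).  Each window's monthly mean enters the baseline
(intrinsic) model as a fixed covariate, with and without an age interaction,
and candidates are ranked by ML-AICc against the baseline.  A randomization
test re-runs the scan on data whose year labels have been permuted to
quantify how much AICc improvement a signal-free climate can produce.

By default candidate models keep the baseline's variance-component estimates
fixed and re-profile only the fixed effects and sigma^2 (the random
*structure* is always the baseline's); `refit_theta=True` re-optimises the
variance components for every candidate.  The selected model should always be
refitted in full afterwards, which is what the pipeline does.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ClimateSeries, GrowthTable
from .errors import CoverageError, ParameterError
from . import lmm
from .lmm import ModelSpec, aicc, build_fixed_design, _term_column

__all__ = [
    "WindowDef",
    "WindowScanResult",
    "RandomizationResult",
    "enumerate_windows",
    "window_aggregate",
    "scan",
    "randomization_test",
    "permute_years",
]


@dataclass(frozen=True)
class WindowDef:
    """A month span: ``open`` months back to ``close`` months back from
    December of the growth year (inclusive; 0 = December itself)."""

    open: int
    close: int

    def __post_init__(self):
        if not (0 <= self.close <= self.open <= 23):
            raise ParameterError(
                f"window must satisfy 0 <= close <= open <= 23, got "
                f"open={self.open}, close={self.close}")

    @property
    def n_months(self) -> int:
        return self.open - self.close + 1


def enumerate_windows(max_back: int = 23) -> list[WindowDef]:
    """All (open, close) spans with close <= open <= max_back;
    there are (max_back+1)(max_back+2)/2 of them."""
    if max_back < 0:
        raise ParameterError("max_back must be >= 0")
    return [WindowDef(o, c) for o in range(max_back + 1) for c in range(o + 1)]


def _window_values(climate: ClimateSeries, window: WindowDef,
                   years: np.ndarray) -> np.ndarray:
    """Mean of the window's monthly values for each growth year."""
    yrs = np.asarray(years, dtype=np.int64)
    t_ref = yrs * 12 + 11  # December
    offs = np.arange(window.close, window.open + 1)
    tidx = t_ref[:, None] - offs[None, :]
    vals = climate.values_at(tidx)
    bad = np.isnan(vals)
    if bad.any():
        miss = sorted({(int(t // 12), int(t % 12) + 1) for t in tidx[bad]})
        raise CoverageError(
            f"climate series lacks {len(miss)} month(s), e.g. "
            f"{miss[:5]}", missing=miss)
    return vals.mean(axis=1)


def window_aggregate(climate: ClimateSeries, window: WindowDef,
                     growth_year: int) -> float:
    """Arithmetic mean of the monthly climate values inside the window."""
    return float(_window_values(climate, window, np.array([growth_year]))[0])


@dataclass
class WindowScanResult:
    table: pd.DataFrame
    baseline_aicc: float
    baseline_theta: np.ndarray | None

    @property
    def best(self) -> pd.Series:
        ok = self.table[self.table["converged"]]
        return ok.loc[ok["aicc"].idxmin()]

    @property
    def best_window(self) -> WindowDef:
        b = self.best
        return WindowDef(int(b["open"]), int(b["close"]))


def scan(frame, climate: ClimateSeries, base_spec: ModelSpec, *,
         max_back: int = 23, interaction: str = "both",
         age_term: str = "log_age_c", refit_theta: bool = False,
         covariate_name: str = "sst_win",
         baseline_fit: "lmm.FitResult | None" = None) -> WindowScanResult:
    """Fit every window x {with, without age interaction} candidate and rank
    by ML-AICc against the intrinsic baseline."""
    if interaction not in ("both", "with", "without"):
        raise ParameterError("interaction must be 'both', 'with' or 'without'")
    df = frame.data if isinstance(frame, GrowthTable) else frame
    base_ml = base_spec.with_method("ML")
    if baseline_fit is None:
        baseline = lmm.fit(base_ml, df)
    else:
        baseline = baseline_fit
    theta = baseline.theta
    y = df[base_ml.response].to_numpy(dtype=float)
    X_base, base_names = build_fixed_design(df, base_ml.fixed)
    p_base = X_base.shape[1]
    years = df["year"].to_numpy()
    inter_col = _term_column(df, age_term)
    inter_opts = {"both": (False, True), "with": (True,), "without": (False,)}[interaction]

    if base_ml.random and not refit_theta:
        groups = lmm._build_groups(df, base_ml.random)
        work = lmm._CrossedLMM(y, X_base, groups)
    else:
        work = None

    rows = []
    n = len(df)
    for w in enumerate_windows(max_back):
        vals = _window_values(climate, w, years)
        vals = vals - vals.mean()
        for inter in inter_opts:
            if work is not None:
                cols = [X_base, vals[:, None]]
                if inter:
                    cols.append((inter_col * vals)[:, None])
                X = np.hstack(cols)
                work.set_X(X)
                sol = work.solve(theta, reml=False, full=False, return_beta=True)
                dev, beta = sol
                k = X.shape[1] + work.n_theta + 1
                a = aicc(-0.5 * dev, k, n)
                coef = float(beta[p_base])
                converged = True
            else:
                df2 = df.copy()
                df2[covariate_name] = vals
                fixed = base_ml.fixed + (covariate_name,)
                if inter:
                    fixed = fixed + (f"{age_term}:{covariate_name}",)
                f = lmm.fit(base_ml.with_fixed(fixed), df2, theta0=theta)
                a = f.aicc
                coef = float(f.beta[covariate_name])
                converged = f.converged
            rows.append({"open": w.open, "close": w.close, "interaction": inter,
                         "aicc": a, "coef": coef, "converged": converged})
    tbl = pd.DataFrame(rows)
    tbl["delta_aicc"] = tbl["aicc"] - baseline.aicc
    return WindowScanResult(table=tbl, baseline_aicc=baseline.aicc,
                            baseline_theta=theta)


@dataclass
class RandomizationResult:
    observed_delta: float
    null_deltas: np.ndarray
    n_rand: int

    @property
    def percentile(self) -> float:
        """Rank-based probability (1 + #{null <= observed}) / (1 + n_rand);
        small values mean the observed AICc gain is rarely matched by
        permuted data."""
        return (1 + int(np.sum(self.null_deltas <= self.observed_delta))) / (1 + self.n_rand)


def permute_years(df: pd.DataFrame, rng: np.random.Generator,
                  unit: str = "fish") -> pd.DataFrame:
    """Break the growth-climate pairing while preserving model structure.

    ``unit='fish'``: fish are grouped by identical age support and their
    cohort labels permuted within group, shifting each fish's whole year
    sequence onto another fish's span (the multiset of year labels and every
    fish's age structure are preserved).  ``unit='record'``: year labels are
    permuted across rows.
    """
    out = df.copy()
    if unit == "record":
        perm = rng.permutation(len(out))
        out["year"] = out["year"].to_numpy()[perm]
        return out
    if unit != "fish":
        raise ParameterError("unit must be 'fish' or 'record'")
    ages = df.groupby("fish_id")["age"].agg(lambda a: tuple(sorted(a)))
    cohorts = df.groupby("fish_id")["cohort"].first()
    new_cohort = cohorts.copy()
    for _, fish in ages.groupby(ages):
        ids = fish.index.to_numpy()
        new_cohort.loc[ids] = rng.permutation(cohorts.loc[ids].to_numpy())
    out["cohort"] = out["fish_id"].map(new_cohort).to_numpy()
    out["year"] = out["cohort"] + out["age"]
    return out


def randomization_test(frame, climate: ClimateSeries, base_spec: ModelSpec, *,
                       n_rand: int = 999, seed: int = 0, unit: str = "fish",
                       max_back: int = 23, interaction: str = "both",
                       age_term: str = "log_age_c",
                       refit_theta: bool = False) -> RandomizationResult:
    """Null distribution of the best scan delta-AICc under permuted year
    labels, and the observed delta's rank-based percentile."""
    if n_rand < 1:
        raise ParameterError("n_rand must be >= 1")
    df = frame.data if isinstance(frame, GrowthTable) else frame
    rng = np.random.default_rng(seed)
    kw = dict(max_back=max_back, interaction=interaction, age_term=age_term,
              refit_theta=refit_theta)
    observed = scan(df, climate, base_spec, **kw)
    obs_delta = float(observed.best["delta_aicc"])
    theta = observed.baseline_theta
    nulls = np.empty(n_rand)
    base_ml = base_spec.with_method("ML")
    for it in range(n_rand):
        dperm = permute_years(df, rng, unit=unit)
        if refit_theta:
            res = scan(dperm, climate, base_spec, **kw)
        else:
            base_fit = lmm.fit(base_ml, dperm, fix_theta=theta)
            res = scan(dperm, climate, base_spec, baseline_fit=base_fit, **kw)
        nulls[it] = float(res.best["delta_aicc"])
    return RandomizationResult(observed_delta=obs_delta, null_deltas=nulls,
                               n_rand=n_rand)
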