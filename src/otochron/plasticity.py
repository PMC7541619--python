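"""Within/among-individual temperature decomposition, individual thermal
reaction norms, and cohort-level plasticity variance.

Within-group centering splits the windowed temperature covariate into each
fish's lifetime mean (the among-individual axis: do fish that lived in
warmer water grow differently?) and the deviations from it (the
within-individual axis: does one fish grow differently in its warmer
years?).  A fish-level random slope on the within component measures
individual plasticity; the spread of its BLUPs within a cohort, correlated
against the cohort's mean environment, addresses whether plasticity
variation itself changes with conditions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GrowthTable
from .errors import AnalysisError, ParameterError
from . import lmm
from .lmm import FitResult, ModelSpec, RandomTerm

__all__ = [
    "CenteredCovariate",
    "PlasticitySummary",
    "decompose",
    "fit_centered_models",
    "fit_random_slopes",
    "percent_change",
    "percent_change_table",
    "cohort_variance_analysis",
    "CohortVarianceResult",
]


@dataclass
class CenteredCovariate:
    """Per-fish lifetime means (among) and per-record deviations (within)."""

    covariate: str
    among: pd.Series          # fish_id -> lifetime mean
    within: np.ndarray        # per record
    n_single_record_fish: int


def decompose(table: GrowthTable, covariate: str = "sst"
              ) -> tuple[GrowthTable, CenteredCovariate]:
    """Exact within/among split: ``among + within`` reconstructs the
    covariate row by row; each fish's within values average to zero.

    Adds ``{covariate}_within``, ``{covariate}_among`` and the mean-centered
    ``{covariate}_among_c`` columns.  Fish with a single retained record get
    within = 0 (counted, allowed)."""
    out = table.copy()
    df = out.data
    if covariate not in df.columns:
        raise ParameterError(f"covariate {covariate!r} not attached")
    x = df[covariate].to_numpy(dtype=float)
    fish_mean = df.groupby("fish_id")[covariate].transform("mean").to_numpy()
    within = x - fish_mean
    df[f"{covariate}_within"] = within
    df[f"{covariate}_among"] = fish_mean
    c = float(fish_mean.mean())
    df[f"{covariate}_among_c"] = fish_mean - c
    out.centering[f"{covariate}_among"] = c
    counts = df.groupby("fish_id").size()
    singles = int((counts == 1).sum())
    among = df.groupby("fish_id")[covariate].mean()
    return out, CenteredCovariate(covariate=covariate, among=among,
                                  within=within, n_single_record_fish=singles)


def _split_terms(fixed, covariate, age_term):
    """Partition baseline fixed terms into non-climate terms and note whether
    the climate covariate carried an age interaction."""
    cov_c = f"{covariate}_c"
    other, had_main, had_inter = [], False, False
    for t in fixed:
        parts = [p.strip() for p in t.split(":")]
        if cov_c in parts:
            if len(parts) == 1:
                had_main = True
            elif age_term in parts:
                had_inter = True
            continue
        other.append(t)
    return other, had_main, had_inter


def fit_centered_models(frame, base_spec: ModelSpec, *, covariate: str = "sst",
                        age_term: str = "log_age_c") -> dict:
    """Fit the two within-group-centering variants and compare with the
    baseline extrinsic model by ML-AICc:

    (a) within + among: the within deviation replaces the original covariate
        (keeping its age interaction if the baseline had one); the among
        term enters as a main effect only.
    (b) original + among: the original covariate stays and the among term is
        added, separating the among-individual axis from the population
        slope.
    """
    df = frame.data if isinstance(frame, GrowthTable) else frame
    ml = base_spec.with_method("ML")
    other, had_main, had_inter = _split_terms(ml.fixed, covariate, age_term)
    if not had_main and not had_inter:
        raise ParameterError(
            f"baseline spec does not contain the {covariate}_c covariate")
    wcol = f"{covariate}_within"
    acol = f"{covariate}_among_c"
    within_var = float(df[wcol].var()) if wcol in df.columns else 0.0
    terms_a = list(other)
    degenerate = within_var == 0
    if not degenerate:
        terms_a += [wcol] + ([f"{age_term}:{wcol}"] if had_inter else [])
    else:
        warnings.warn("within-individual deviations are identically zero; "
                      "dropping the within term")
    terms_a.append(acol)

    baseline = lmm.fit(ml, df)
    fit_a = lmm.fit(ml.with_fixed(terms_a), df, theta0=baseline.theta)
    fits = [baseline, fit_a]
    names = ["baseline", "within+among"]
    fit_b = None
    if not degenerate:
        # with within == 0 the original covariate equals the among term and
        # variant (b) is not identified
        fit_b = lmm.fit(ml.with_fixed(list(ml.fixed) + [acol]), df,
                        theta0=baseline.theta)
        fits.append(fit_b)
        names.append("original+among")
    table = lmm.compare(fits, names=names)
    return {"baseline": baseline, "within_among": fit_a,
            "original_among": fit_b, "comparison": table}


@dataclass
class PlasticitySummary:
    """Per-fish thermal reaction-norm slopes and their dispersion."""

    fish: pd.DataFrame        # fish_id, cohort, slope_blup, slope_se, slope_total
    beta_within: float
    var_slope: float
    singular: bool


def fit_random_slopes(frame, centered_spec: ModelSpec, *,
                      covariate: str = "sst", correlated: bool = False,
                      theta0: np.ndarray | None = None,
                      fish_group: str = "fish_id"
                      ) -> tuple[FitResult, PlasticitySummary]:
    """Extend the centered model with a fish-level random slope on the
    within-individual component and summarise the per-fish slopes.

    ``slope_blup`` is the fish's BLUP deviation; ``slope_total`` adds the
    population (fixed) within slope.  A boundary fit (slope variance ~ 0)
    still yields a summary, flagged as singular."""
    df = frame.data if isinstance(frame, GrowthTable) else frame
    wcol = f"{covariate}_within"
    if correlated:
        random = tuple(
            RandomTerm(rt.group, rt.intercept, rt.slopes + (wcol,), rt.correlated)
            if rt.group == fish_group else rt
            for rt in centered_spec.random)
    else:
        random = centered_spec.random + (
            RandomTerm(fish_group, intercept=False, slopes=(wcol,),
                       correlated=False),)
    spec = ModelSpec(response=centered_spec.response, fixed=centered_spec.fixed,
                     random=random, method=centered_spec.method)
    fit_res = lmm.fit(spec, frame, theta0=theta0)
    blups = lmm.blup_extract(fit_res, fish_group, wcol)
    beta_w = float(fit_res.beta[wcol]) if wcol in fit_res.beta.index else 0.0
    vc = fit_res.varcomps[fish_group]
    var_slope = float(vc["tau"][vc["effects"].index(wcol)])
    cohorts = df.groupby(fish_group)["cohort"].first()
    fish = pd.DataFrame({
        "fish_id": blups["level"],
        "cohort": blups["level"].map(cohorts).to_numpy(),
        "slope_blup": blups["blup"],
        "slope_se": blups["se"],
        "slope_total": beta_w + blups["blup"],
    })
    summary = PlasticitySummary(fish=fish, beta_within=beta_w,
                                var_slope=var_slope,
                                singular=fit_res.singular)
    return fit_res, summary


def percent_change(beta_main: float, beta_age_interaction: float,
                   centered_log_age: float,
                   env_range: tuple[float, float]) -> float:
    """Growth response over an environmental range, as percent change:
    100 (exp[(b_main + b_int * centered ln age)(high - low)] - 1)."""
    lo, hi = env_range
    slope = beta_main + beta_age_interaction * centered_log_age
    return 100.0 * (np.exp(slope * (hi - lo)) - 1.0)


def percent_change_table(fit_res: FitResult, term: str, env_range,
                         interaction_term: str | None = None,
                         ages=range(2, 11),
                         c_age: float | None = None) -> pd.DataFrame:
    """Per-age percent change predicted by a fitted model for one covariate
    over an observed environmental range (the layout of an effects table).
    """
    if c_age is None:
        c_age = fit_res.centering.get("log_age")
        if c_age is None:
            raise ParameterError("no log-age centering constant available")
    b_main = float(fit_res.beta[term])
    b_int = (float(fit_res.beta[interaction_term])
             if interaction_term and interaction_term in fit_res.beta.index else 0.0)
    rows = [{"age": a,
             "percent_change": percent_change(b_main, b_int,
                                              np.log(a) - c_age, env_range)}
            for a in ages]
    return pd.DataFrame(rows)


@dataclass
class CohortVarianceResult:
    table: pd.DataFrame           # cohort, n_fish, var_slope, env means
    correlations: pd.DataFrame    # variable, r, df, p
    n_excluded_cohorts: int


def cohort_variance_analysis(summary: PlasticitySummary, frame, *,
                             env_vars: tuple[str, ...] = ("sst", "n_index", "hr"),
                             min_fish: int = 6,
                             use_total: bool = False) -> CohortVarianceResult:
    """Per-cohort variance of individual slope BLUPs (cohorts with more than
    five fish), correlated with the cohort's mean environment (Pearson r,
    df = #cohorts - 2, two-sided p)."""
    df = frame.data if isinstance(frame, GrowthTable) else frame
    col = "slope_total" if use_total else "slope_blup"
    per = summary.fish.groupby("cohort").agg(
        n_fish=("fish_id", "size"), var_slope=(col, lambda s: s.var(ddof=1)))
    eligible = per[per["n_fish"] >= min_fish].copy()
    n_excluded = int(len(per) - len(eligible))
    if len(eligible) < 3:
        raise AnalysisError(
            f"only {len(eligible)} cohorts with >= {min_fish} fish; need >= 3")
    env = df.groupby("cohort")[[v for v in env_vars if v in df.columns]].mean()
    tbl = eligible.join(env, how="left").reset_index()
    rows = []
    for v in env_vars:
        if v not in tbl.columns:
            continue
        if tbl["var_slope"].std() == 0 or tbl[v].std() == 0:
            # a fully shrunk (singular) slope fit or constant environment
            # leaves nothing to correlate
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(tbl["var_slope"], tbl[v])
        rows.append({"variable": v, "r": float(r),
                     "df": len(tbl) - 2, "p": float(p)})
    return CohortVarianceResult(table=tbl, correlations=pd.DataFrame(rows),
                                n_excluded_cohorts=n_excluded)
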