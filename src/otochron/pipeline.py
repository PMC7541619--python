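"""End-to-end biochronology pipeline.

Drives the four-stage protocol from a config mapping: (1) select the random
structure by REML-AICc with the full intrinsic fixed part, (2) select the
intrinsic fixed part by ML-AICc, (3) find the climate window by sliding-
window scan (with a randomization check) and select the extrinsic fixed
part, (4) decompose the climate covariate, add individual random slopes and
analyse cohort-level plasticity variance.  Emits the year/cohort BLUP
chronology and one artifact file per stage; everything is deterministic
given the config seeds.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ClimateSeries, GrowthTable, StockSeries
from .errors import OtochronError, ParameterError, SpecificationError
from . import lmm, plasticity, prep, simulate, windows
from .lmm import ModelSpec, RandomTerm
from .windows import WindowDef

__all__ = ["PipelineConfig", "Chronology", "run", "export_chronology"]

log = logging.getLogger("otochron")


@dataclass
class PipelineConfig:
    """Either a simulation block or data paths, plus stage settings."""

    simulation: dict | None = None
    data: dict | None = None          # paths: increments, climate, n_index, hr
    seed: int = simulate.DEFAULT_SEED
    max_back: int = 23
    n_rand: int = 199
    interaction: str = "both"
    scan_refit_theta: bool = False
    min_obs_chronology: int = 10
    age_cap: int = 10

    def __post_init__(self):
        if (self.simulation is None) == (self.data is None):
            raise ParameterError(
                "config must have exactly one of 'simulation' or 'data'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Chronology:
    """Year and cohort BLUP series with observation counts; rows with fewer
    than the threshold number of observations are flagged."""

    year: pd.DataFrame
    cohort: pd.DataFrame
    min_obs: int


def export_chronology(fit_res: lmm.FitResult, frame, min_obs: int = 10) -> Chronology:
    df = frame.data if isinstance(frame, GrowthTable) else frame
    out = {}
    for grp, col in (("year", "year"), ("cohort", "cohort")):
        if col not in {g for g in fit_res.varcomps}:
            raise SpecificationError(f"fit lacks a random effect for {col!r}")
        blups = lmm.blup_extract(fit_res, col, "1")
        counts = df[col].value_counts()
        tbl = blups.rename(columns={"level": col})
        tbl["n_obs"] = tbl[col].map(counts).fillna(0).astype(int)
        tbl["flagged"] = tbl["n_obs"] < min_obs
        out[grp] = tbl.sort_values(col).reset_index(drop=True)
    return Chronology(year=out["year"], cohort=out["cohort"], min_obs=min_obs)


def _simulate_inputs(cfg: PipelineConfig):
    sim = dict(cfg.simulation)
    seed = int(sim.get("seed", cfg.seed))
    ss = np.random.SeedSequence(seed)
    s_clim, s_pop, s_stock, s_truth = [int(s.generate_state(1)[0] % (2**31))
                                       for s in ss.spawn(4)]
    years = sim.get("catch_years", (1960, 2015))
    catch_years = range(int(years[0]), int(years[1]) + 1)
    clim_start = int(sim.get("climate_start", min(catch_years) - 20))
    clim_end = int(sim.get("climate_end", max(catch_years) + 1))
    climate = simulate.simulate_climate(clim_start, clim_end, seed=s_clim)
    roster = simulate.simulate_population(
        int(sim.get("n_fish", 500)), catch_years,
        age_at_catch_range=tuple(sim.get("age_at_catch_range", (8, 12))),
        seed=s_pop)
    stock_years = range(clim_start, clim_end + 1)
    stock = simulate.simulate_stock(stock_years, seed=s_stock)
    truth_kw = dict(sim.get("truth", {}))
    truth = simulate.SimulationTruth(seed=s_truth, **truth_kw)
    window = WindowDef(*sim.get("window", (8, 8)))
    table, info = simulate.simulate_increments(
        truth, roster, climate, stock, window=window, age_cap=cfg.age_cap)
    return table, climate, stock, truth, info


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.data
    table = GrowthTable.from_csv(paths["increments"])
    climate = ClimateSeries.from_csv(paths["climate"])
    stock = None
    if "n_index" in paths and "hr" in paths:
        stock = StockSeries.from_csv(paths["n_index"], paths["hr"])
    return table, climate, stock, None, None


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _intercept_only_iccs(table) -> dict:
    """Per-factor ICCs, each from its own single-factor intercept-only
    model (joint year+cohort intercept-only models are age-period-cohort
    aliased: year - cohort reproduces the age trend)."""
    out = {}
    for g in ("fish_id", "year", "cohort"):
        f0 = lmm.fit(ModelSpec("log_width", (), (RandomTerm(g),), "REML"),
                     table)
        out[g] = lmm.icc(f0, g)
    return out


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the full protocol; writes artifacts under ``outdir`` and
    returns the result bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        # ---- data ----
        stage = "data"
        if config.simulation is not None:
            table, climate, stock, truth, info = _simulate_inputs(config)
            if truth is not None:
                truth.to_json(out / "truth.json")
        else:
            table, climate, stock, truth, info = _load_inputs(config)
        log.info("data: %d rows, %d fish", len(table), table.data["fish_id"].nunique())

        # ---- prep ----
        stage = "prep"
        table = prep.apply_filters(table, age_cap=config.age_cap)
        _write_json(out / "filter_report.json", table.filter_report)
        table = prep.transform(table)
        df_has_sex = "sex" in table.data.columns and table.data["sex"].nunique() == 2
        results["n_obs"] = len(table)

        # ---- step 1a: random structure (REML-AICc, full intrinsic fixed) ----
        stage = "random_structure"
        fixed_full = ("log_age_c",) + (("sex", "log_age_c:sex") if df_has_sex else ())
        cand_random, cand_names = [], []
        for slopes in itertools.product([False, True], repeat=3):
            terms = tuple(
                RandomTerm(g, intercept=True,
                           slopes=("log_age_c",) if s else ())
                for g, s in zip(("fish_id", "year", "cohort"), slopes))
            cand_random.append(terms)
            cand_names.append("+".join(
                f"{g}{'(age)' if s else ''}"
                for g, s in zip(("F", "Y", "C"), slopes)))
        fits = [lmm.fit(ModelSpec("log_width", fixed_full, r, "REML"), table)
                for r in cand_random]
        rs_tbl = lmm.compare(fits, names=cand_names)
        _tsv(rs_tbl, out / "random_selection.tsv")
        best_random = cand_random[cand_names.index(rs_tbl.iloc[0]["name"])]
        log.info("random structure: %s", rs_tbl.iloc[0]["name"])

        # ---- step 1b: intrinsic fixed part (ML-AICc) ----
        stage = "intrinsic_fixed"
        cand_fixed = [("log_age_c",)]
        if df_has_sex:
            cand_fixed += [("log_age_c", "sex"), ("log_age_c", "sex", "log_age_c:sex")]
        ifits = [lmm.fit(ModelSpec("log_width", f, best_random, "ML"), table)
                 for f in cand_fixed]
        if len(ifits) > 1:
            int_tbl = lmm.compare(ifits, names=["+".join(f) for f in cand_fixed])
            _tsv(int_tbl, out / "intrinsic_selection.tsv")
            best_fixed = cand_fixed[["+".join(f) for f in cand_fixed]
                                    .index(int_tbl.iloc[0]["name"])]
        else:
            best_fixed = cand_fixed[0]
        intrinsic = ModelSpec("log_width", best_fixed, best_random, "ML")
        results["intrinsic_fixed"] = best_fixed
        log.info("intrinsic fixed: %s", best_fixed)

        # ---- chronology from intercept-only year/cohort model ----
        stage = "chronology"
        chron_random = tuple(
            RandomTerm(rt.group, rt.intercept,
                       () if rt.group in ("year", "cohort") else rt.slopes,
                       rt.correlated)
            for rt in best_random)
        chron_fit = lmm.fit(ModelSpec("log_width", best_fixed, chron_random,
                                      "REML"), table)
        chron = export_chronology(chron_fit, table, config.min_obs_chronology)
        _tsv(chron.year, out / "chronology_year.tsv")
        _tsv(chron.cohort, out / "chronology_cohort.tsv")
        results["chronology"] = chron

        # ---- step 2: climate window scan + randomization ----
        stage = "window_scan"
        scan_res = windows.scan(
            table, climate, intrinsic, max_back=config.max_back,
            interaction=config.interaction,
            refit_theta=config.scan_refit_theta)
        _tsv(scan_res.table, out / "window_scan.tsv")
        best = scan_res.best
        best_window = scan_res.best_window
        results["best_window"] = best_window
        log.info("best window: back %d..%d, interaction=%s, dAICc=%.2f",
                 best_window.open, best_window.close, best["interaction"],
                 best["delta_aicc"])
        rand = windows.randomization_test(
            table, climate, intrinsic, n_rand=config.n_rand,
            seed=int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31)),
            max_back=config.max_back, interaction=config.interaction,
            refit_theta=config.scan_refit_theta)
        _write_json(out / "randomization.json", {
            "observed_delta": rand.observed_delta,
            "percentile": rand.percentile, "n_rand": rand.n_rand})
        pd.DataFrame({"null_delta": rand.null_deltas}).to_csv(
            out / "null_deltas.tsv", sep="\t", index=False)
        results["randomization_percentile"] = rand.percentile

        # ---- step 2b: extrinsic fixed part (ML-AICc) ----
        stage = "extrinsic_fixed"
        table = prep.attach_covariates(table, climate, best_window,
                                       stock if stock is not None else None)
        table = prep.transform(table)
        sst_terms = ("sst_c",) + (("log_age_c:sst_c",) if best["interaction"] else ())
        options = {
            "n_index": [(), ("n_index_c",), ("n_index_c", "log_age_c:n_index_c")],
            "hr": [(), ("hr_c",), ("hr_c", "log_age_c:hr_c")],
        }
        have = {k: v for k, v in options.items() if k in table.data.columns}
        cand, names = [best_fixed], ["intrinsic_only"]
        for combo in itertools.product(*have.values()):
            extra = tuple(t for c in combo for t in c)
            cand.append(best_fixed + sst_terms + extra)
            names.append("sst+" + "+".join(extra) if extra else "sst_only")
        efits = [lmm.fit(ModelSpec("log_width", f, best_random, "ML"), table,
                         theta0=fits[cand_names.index(rs_tbl.iloc[0]["name"])].theta)
                 for f in cand]
        ext_tbl = lmm.compare(efits, names=names)
        _tsv(ext_tbl, out / "extrinsic_selection.tsv")
        extrinsic_fixed = cand[names.index(ext_tbl.iloc[0]["name"])]
        extrinsic = ModelSpec("log_width", extrinsic_fixed, best_random, "ML")
        extrinsic_fit = efits[names.index(ext_tbl.iloc[0]["name"])]
        results["extrinsic_fixed"] = extrinsic_fixed
        log.info("extrinsic fixed: %s", extrinsic_fixed)

        if "sst_c" not in extrinsic_fixed:
            # no supported climate signal: plasticity stages are moot
            log.info("no climate term selected; skipping centering/plasticity")
            _write_json(out / "centered_comparison.json",
                        {"skipped": "no climate term selected"})
            stage = "final"
            r2m, r2c = lmm.r2_nakagawa(extrinsic_fit)
            iccs = _intercept_only_iccs(table)
            _write_json(out / "diagnostics.json", {
                "r2_marginal": r2m, "r2_conditional": r2c, "icc": iccs})
            results["r2"] = (r2m, r2c)
            results["icc"] = iccs
            _write_json(out / "config.json", {
                "seed": config.seed, "max_back": config.max_back,
                "n_rand": config.n_rand,
                "centering": {k: float(v) for k, v in table.centering.items()}})
            return results

        # ---- step 3: within-group centering ----
        stage = "centering"
        table, centered = plasticity.decompose(table, "sst")
        cm = plasticity.fit_centered_models(table, extrinsic)
        _tsv(cm["comparison"], out / "centered_comparison.tsv")
        results["centered_comparison"] = cm["comparison"]
        centered_spec = cm["within_among"].spec

        # ---- step 4: individual random slopes ----
        stage = "random_slopes"
        base_reml = centered_spec.with_method("REML")
        no_slope = lmm.fit(base_reml, table)
        ext_fit, summary = plasticity.fit_random_slopes(
            table, base_reml, covariate="sst", theta0=None)
        h2_tbl = lmm.compare([no_slope, ext_fit],
                             names=["no_random_slope", "random_slope"])
        _tsv(h2_tbl, out / "random_slope_comparison.tsv")
        _tsv(summary.fish, out / "plasticity_fish.tsv")
        _write_json(out / "extended_fit.json", ext_fit.to_dict())
        results["extended_fit"] = ext_fit
        results["plasticity"] = summary
        results["h2_comparison"] = h2_tbl

        # ---- cohort-level plasticity variance ----
        stage = "cohort_variance"
        try:
            cv = plasticity.cohort_variance_analysis(summary, table)
            _tsv(cv.table, out / "cohort_variance.tsv")
            _write_json(out / "cohort_correlations.json",
                        cv.correlations.to_dict(orient="records"))
            results["cohort_variance"] = cv
        except OtochronError as e:
            log.warning("cohort variance analysis skipped: %s", e)
            _write_json(out / "cohort_correlations.json", {"skipped": str(e)})

        # ---- final refits and diagnostics ----
        stage = "final"
        std_fit = lmm.standardized_refit(ext_fit.spec, table)
        _write_json(out / "standardized_fit.json", std_fit.to_dict())
        r2m, r2c = lmm.r2_nakagawa(ext_fit)
        iccs = _intercept_only_iccs(table)
        vifs = lmm.vif(table, [t for t in ext_fit.spec.fixed])
        _write_json(out / "diagnostics.json", {
            "r2_marginal": r2m, "r2_conditional": r2c, "icc": iccs,
            "vif": vifs.to_dict()})
        results["r2"] = (r2m, r2c)
        results["icc"] = iccs
        _write_json(out / "config.json", {
            "seed": config.seed, "max_back": config.max_back,
            "n_rand": config.n_rand,
            "centering": {k: float(v) for k, v in table.centering.items()}})
        return results
    except OtochronError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise OtochronError(f"pipeline stage {stage!r} failed: {e}") from e
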