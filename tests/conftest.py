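"""Shared fixtures: small synthetic datasets and fitted models reused across
test modules (module/session scope keeps total fit count low)."""
import numpy as np
import pandas as pd
import pytest

import otochron as oc


@pytest.fixture(scope="session")
def small_prepared():
    """~80 fish, prepared (filtered + transformed) frame."""
    roster = oc.simulate_population(80, range(1990, 2001), seed=2)
    truth = oc.SimulationTruth(seed=5)
    clim = oc.simulate_climate(1960, 2002, seed=3)
    table, info = oc.simulate_increments(truth, roster, clim)
    return oc.transform(table), truth, info


@pytest.fixture(scope="session")
def intrinsic_spec():
    return oc.ModelSpec(
        "log_width", ("log_age_c",),
        (oc.RandomTerm("fish_id", slopes=("log_age_c",)),
         oc.RandomTerm("year", slopes=("log_age_c",)),
         oc.RandomTerm("cohort", slopes=("log_age_c",))),
        "REML")


@pytest.fixture(scope="session")
def small_fit(small_prepared, intrinsic_spec):
    table, _, _ = small_prepared
    return oc.fit(intrinsic_spec, table)


@pytest.fixture(scope="session")
def extended_setup():
    """Moderate dataset with climate + stock covariates attached and
    decomposed, plus the extended-model spec (used by several modules)."""
    roster = oc.simulate_population(300, range(1950, 2011),
                                    age_at_catch_range=(8, 10), seed=21)
    clim = oc.simulate_climate(1920, 2011, seed=22)
    stock = oc.simulate_stock(range(1920, 2012), seed=23)
    truth = oc.SimulationTruth(seed=24)
    table, info = oc.simulate_increments(truth, roster, clim, stock)
    table = oc.attach_covariates(table, clim, oc.WindowDef(8, 8), stock)
    table, _ = oc.decompose(table, "sst")
    table = oc.transform(table)
    fixed = ("log_age_c", "sst_within", "log_age_c:sst_within", "sst_among_c",
             "n_index_c", "log_age_c:n_index_c")
    random = (oc.RandomTerm("fish_id", slopes=("log_age_c",)),
              oc.RandomTerm("year", slopes=("log_age_c",)),
              oc.RandomTerm("cohort", slopes=("log_age_c",)))
    centered_spec = oc.ModelSpec("log_width", fixed, random, "REML")
    return {"table": table, "truth": truth, "info": info, "climate": clim,
            "stock": stock, "roster": roster, "centered_spec": centered_spec}


@pytest.fixture(scope="session")
def extended_fit(extended_setup):
    fit_res, summary = oc.fit_random_slopes(
        extended_setup["table"], extended_setup["centered_spec"])
    return fit_res, summary


def one_way_frame(n_groups: int, per_group: int, tau: float, sigma2: float,
                  seed: int, mu: float = 0.0) -> pd.DataFrame:
    """Balanced one-way random-effects layout (used by closed-form checks)."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    b = rng.normal(0, np.sqrt(tau), n_groups)
    y = mu + b[g] + rng.normal(0, np.sqrt(sigma2), len(g))
    return pd.DataFrame({"y": y, "g": g})
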