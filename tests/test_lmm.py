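"""Mixed-model engine: closed forms, oracle equivalence, and independent
cross-checks against statsmodels (one factor) and lme4 (crossed factors)."""
import subprocess

import numpy as np
import pandas as pd
import pytest

import otochron as oc
from otochron.errors import ComparisonError, ParameterError, SpecificationError

from conftest import one_way_frame


class TestOlsDegenerate:
    def test_matches_least_squares(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        for method, dfree in (("ML", 50), ("REML", 48)):
            res = oc.fit(oc.ModelSpec("y", ("x",), (), method), df)
            X = np.column_stack([np.ones(50), df["x"]])
            beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
            assert np.allclose(res.beta.to_numpy(), beta)
            rss = np.sum((df["y"] - X @ beta) ** 2)
            assert res.sigma2 == pytest.approx(rss / dfree)

    def test_rank_deficient_names_terms(self):
        df = pd.DataFrame({"y": np.arange(6.0), "a": np.arange(6.0),
                           "b": 2 * np.arange(6.0)})
        with pytest.raises(SpecificationError, match="collinear"):
            oc.fit(oc.ModelSpec("y", ("a", "b"), (), "ML"), df)


class TestOneWayClosedForm:
    def test_balanced_anova_estimators(self):
        # REML in a balanced one-way layout reproduces the ANOVA
        # variance-component estimators (interior optimum)
        df = one_way_frame(40, 5, tau=1.0, sigma2=0.5, seed=3)
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
        m = df.groupby("g")["y"].mean()
        n_i = 5
        msb = n_i * ((m - m.mean()) ** 2).sum() / (len(m) - 1)
        msw = df.groupby("g")["y"].apply(
            lambda s: ((s - s.mean()) ** 2).sum()).sum() / (len(df) - len(m))
        assert res.sigma2 == pytest.approx(msw, rel=1e-5)
        assert res.varcomps["g"]["tau"][0] == pytest.approx((msb - msw) / n_i,
                                                            rel=1e-4)


class TestAicc:
    def test_closed_form(self):
        assert oc.aicc(-100, 5, 100) == pytest.approx(210.6383, abs=1e-4)

    def test_large_n_limit(self):
        assert oc.aicc(-100, 5, 10 ** 9) == pytest.approx(210.0, abs=1e-6)

    def test_degenerate_zero(self):
        assert oc.aicc(0, 0, 10) == 0

    def test_undefined_correction(self):
        with pytest.raises(ParameterError):
            oc.aicc(-10, 9, 10)


class TestOracle:
    def test_single_standard_normal_observation(self):
        df = pd.DataFrame({"y": [0.0]})
        spec = oc.ModelSpec("y", (), (), "ML")
        ll = oc.loglik_oracle(spec, df, {"sigma2": 1.0, "beta": [0.0]})
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_matches_fitter_objective_at_optimum(self, small_prepared,
                                                 intrinsic_spec, small_fit):
        table, _, _ = small_prepared
        ll = oc.loglik_oracle(intrinsic_spec, table, small_fit.params)
        assert ll == pytest.approx(small_fit.loglik, rel=1e-10)

    def test_block_additivity_over_independent_groups(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.normal(size=30),
                           "g": np.repeat([0, 1, 2, 3, 4, 5], 5)})
        spec = oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "ML")
        params = {"sigma2": 0.8, "Sigma": {"g": [[0.4]]}, "beta": [0.0]}
        whole = oc.loglik_oracle(spec, df, params)
        parts = sum(
            oc.loglik_oracle(spec, df[df["g"].isin(h)].reset_index(drop=True),
                             params)
            for h in ([0, 1, 2], [3, 4, 5]))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_rejects_bad_sigma(self, small_prepared, intrinsic_spec):
        table, _, _ = small_prepared
        with pytest.raises(ParameterError):
            oc.loglik_oracle(intrinsic_spec, table,
                             {"sigma2": -1.0, "Sigma": {}})


class TestIcc:
    def test_formula(self):
        df = one_way_frame(30, 4, tau=1.0, sigma2=0.5, seed=2)
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
        t00 = res.varcomps["g"]["tau"][0]
        assert oc.icc(res, "g") == pytest.approx(t00 / (t00 + res.sigma2))

    def test_zero_tau_gives_zero(self):
        df = one_way_frame(30, 4, tau=0.0, sigma2=1.0, seed=7)
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
        assert oc.icc(res, "g") <= 1e-6

    def test_unknown_group_rejected(self, small_fit):
        with pytest.raises(SpecificationError):
            oc.icc(small_fit, "nope")

    def test_recovery_at_fish_icc_scale(self):
        # single factor with tau/(tau+sigma2) = 0.134: the share of growth
        # variance attributable to individual identity
        target = 0.134
        tau, s2 = 0.134, 0.866
        vals = []
        for seed in range(10):
            df = one_way_frame(1000, 5, tau=tau, sigma2=s2, seed=seed)
            res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
            vals.append(oc.icc(res, "g"))
        assert abs(np.mean(vals) - target) < 0.03


class TestR2:
    def test_component_formula(self):
        assert oc.r2_components(1.0, 1.0, 2.0) == pytest.approx((0.25, 0.5))

    def test_perfect_ols_fit_approaches_one(self):
        x = np.linspace(0, 1, 40)
        df = pd.DataFrame({"y": 2 * x + 1, "x": x})
        res = oc.fit(oc.ModelSpec("y", ("x",), (), "ML"), df)
        r2m, r2c = oc.r2_nakagawa(res)
        assert r2m > 0.999999 and r2c > 0.999999

    def test_intercept_only_marginal_zero(self, small_prepared):
        table, _, _ = small_prepared
        res = oc.fit(oc.ModelSpec("log_width", (),
                                  (oc.RandomTerm("fish_id"),), "REML"), table)
        r2m, r2c = oc.r2_nakagawa(res)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert 0 <= r2m <= r2c <= 1

    def test_ordering_invariant(self, small_fit):
        r2m, r2c = oc.r2_nakagawa(small_fit)
        assert 0 <= r2m <= r2c <= 1


class TestBlup:
    def one_group_frame(self):
        # two groups of 4, group means exactly +1 and -1
        return pd.DataFrame({
            "y": [1.0] * 4 + [-1.0] * 4,
            "g": [0] * 4 + [1] * 4,
        })

    def test_one_way_shrinkage_closed_form(self):
        # relative factor fixed at 1 => tau = sigma^2, shrinkage
        # d * tau / (tau + sigma2/n_i) = 0.8 d
        df = self.one_group_frame()
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "ML"), df,
                     fix_theta=np.array([1.0]))
        b = oc.blup_extract(res, "g", "1").set_index("level")["blup"]
        assert b[0] == pytest.approx(0.8, rel=1e-10)
        assert b[1] == pytest.approx(-0.8, rel=1e-10)

    def test_zero_tau_full_shrinkage(self):
        df = self.one_group_frame()
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "ML"), df,
                     fix_theta=np.array([0.0]))
        b = oc.blup_extract(res, "g", "1")["blup"]
        assert np.allclose(b, 0.0)

    def test_balanced_blups_sum_to_zero(self):
        df = one_way_frame(12, 6, tau=0.8, sigma2=0.4, seed=9)
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
        b = oc.blup_extract(res, "g", "1")["blup"]
        assert abs(b.sum()) < 1e-8 * b.abs().sum()

    def test_unknown_effect_rejected(self, small_fit):
        with pytest.raises(SpecificationError):
            oc.blup_extract(small_fit, "fish_id", "nope")

    def test_shrinkage_towards_zero(self, small_prepared, small_fit):
        table, _, _ = small_prepared
        b = oc.blup_extract(small_fit, "year", "1")
        raw = (table.data.groupby("year")["log_width"].mean()
               - table.data["log_width"].mean())
        merged = b.set_index("level").join(raw.rename("raw"))
        assert (merged["blup"].abs() <= merged["raw"].abs() + 1e-6).mean() > 0.9


class TestCompare:
    def make(self, aiccs_ks):
        fits = []
        for a, k in aiccs_ks:
            f = oc.FitResult(
                spec=oc.ModelSpec("y", (), (), "ML"), method="ML",
                beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
                ci=pd.DataFrame(columns=["lower", "upper"]), sigma2=1.0,
                varcomps={}, theta=None, loglik=0.0, n_obs=100, n_fixed=1,
                n_params=k, aicc=a, converged=True, singular=False)
            fits.append(f)
        return fits

    def test_ranking_and_delta(self):
        tbl = oc.compare(self.make([(100, 5), (105, 6)]), names=["a", "b"])
        assert tbl["name"].tolist() == ["a", "b"]
        assert tbl["delta_aicc"].tolist() == [0.0, 5.0]
        assert tbl["rank"].tolist() == [1, 2]

    def test_parsimony_tie_rule(self):
        tbl = oc.compare(self.make([(100, 8), (101.5, 6)]), names=["big", "small"])
        assert tbl.iloc[0]["name"] == "small"

    def test_reml_fixed_mismatch_rejected(self, small_prepared):
        table, _, _ = small_prepared
        f1 = oc.fit(oc.ModelSpec("log_width", ("log_age_c",),
                                 (oc.RandomTerm("fish_id"),), "REML"), table)
        f2 = oc.fit(oc.ModelSpec("log_width", (),
                                 (oc.RandomTerm("fish_id"),), "REML"), table)
        with pytest.raises(ComparisonError):
            oc.compare([f1, f2])


class TestStandardized:
    def test_scale_invariance(self, small_prepared):
        table, _, _ = small_prepared
        df = table.data.copy()
        df["x10"] = 10 * df["log_age_c"]
        s1 = oc.standardized_refit(
            oc.ModelSpec("log_width", ("log_age_c",),
                         (oc.RandomTerm("fish_id"),), "ML"), df)
        s2 = oc.standardized_refit(
            oc.ModelSpec("log_width", ("x10",),
                         (oc.RandomTerm("fish_id"),), "ML"), df)
        assert s1.beta.iloc[1] == pytest.approx(s2.beta.iloc[1], rel=1e-6)

    def test_effect_size_ordering_recovered(self):
        # standardized coefficients order like the generating standardized
        # effect sizes, whatever the raw covariate scales
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(10):
            n = 400
            x1 = rng.normal(0, 5.0, n)   # large raw scale, strong effect
            x2 = rng.normal(0, 0.1, n)   # small raw scale, weak effect
            y = 0.08 * x1 + 2.0 * x2 + rng.normal(0, 0.4, n)
            # standardized truth: 0.08*5 = 0.40 vs 2.0*0.1 = 0.20
            df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            s = oc.standardized_refit(oc.ModelSpec("y", ("x1", "x2"), (),
                                                   "ML"), df)
            hits += abs(s.beta["x1"]) > abs(s.beta["x2"])
        assert hits == 10

    def test_intercept_near_zero(self, small_prepared):
        table, _, _ = small_prepared
        s = oc.standardized_refit(
            oc.ModelSpec("log_width", ("log_age_c",),
                         (oc.RandomTerm("fish_id"),), "ML"), table)
        # the GLS intercept of a z-scored response deviates from zero only
        # through the random-effect weighting
        assert abs(s.beta["(Intercept)"]) < 1e-2


class TestVif:
    def orthonormal_pair(self, n=40):
        rng = np.random.default_rng(4)
        z1 = rng.normal(size=n)
        z1 -= z1.mean()
        z1 /= np.linalg.norm(z1)
        z2 = rng.normal(size=n)
        z2 -= z2.mean()
        z2 -= z1 * (z1 @ z2)
        z2 /= np.linalg.norm(z2)
        return z1, z2

    def test_orthogonal_predictors(self):
        z1, z2 = self.orthonormal_pair()
        df = pd.DataFrame({"a": z1, "b": z2})
        v = oc.vif(df, ["a", "b"])
        assert np.allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_predictor_infinite(self):
        z1, _ = self.orthonormal_pair()
        df = pd.DataFrame({"a": z1, "b": z1})
        v = oc.vif(df, ["a", "b"])
        assert np.isinf(v).all()

    def test_correlation_point_six(self):
        z1, z2 = self.orthonormal_pair()
        df = pd.DataFrame({"a": z1, "b": 0.6 * z1 + 0.8 * z2})
        v = oc.vif(df, ["a", "b"])
        assert np.allclose(v.to_numpy(), 1.5625, atol=1e-10)

    def test_needs_two_terms(self):
        df = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ParameterError):
            oc.vif(df, ["a"])


class TestReml:
    def test_invariant_under_covariate_shift(self, small_prepared):
        table, _, _ = small_prepared
        df = table.data.copy()
        spec = oc.ModelSpec("log_width", ("log_age_c",),
                            (oc.RandomTerm("fish_id", slopes=("log_age_c",)),),
                            "REML")
        f1 = oc.fit(spec, df)
        df2 = df.copy()
        df2["log_age_c"] = df2["log_age_c"] + 5.0
        f2 = oc.fit(spec, df2)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)
        assert f1.sigma2 == pytest.approx(f2.sigma2, rel=1e-4)

    def test_ml_vs_reml_betas_close_at_scale(self, extended_setup, extended_fit):
        fit_reml, _ = extended_fit
        fit_ml = oc.fit(fit_reml.spec.with_method("ML"),
                        extended_setup["table"], theta0=fit_reml.theta)
        for term in ("log_age_c", "sst_among_c"):
            assert fit_ml.beta[term] == pytest.approx(fit_reml.beta[term],
                                                      rel=0.05)


class TestCrossChecks:
    def test_statsmodels_single_factor(self):
        import statsmodels.formula.api as smf
        df = one_way_frame(60, 5, tau=0.6, sigma2=0.3, seed=13)
        ours = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
        sm_fit = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
        assert ours.loglik >= sm_fit.llf - 1e-4
        assert ours.varcomps["g"]["tau"][0] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert ours.sigma2 == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_lme4_crossed_design(self, small_prepared, intrinsic_spec,
                                 small_fit, tmp_path):
        table, _, _ = small_prepared
        csv = tmp_path / "tab.csv"
        table.data.to_csv(csv, index=False)
        r_code = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- lmer(log_width ~ log_age_c + (1+log_age_c|fish_id) + (1+log_age_c|year)
          + (1+log_age_c|cohort), data=d, REML=TRUE,
          control=lmerControl(optimizer="bobyqa",
                              optCtrl=list(maxfun=100000)))
vc <- as.data.frame(VarCorr(m))
cat(as.numeric(logLik(m)), sigma(m)^2,
    vc$vcov[vc$grp=="fish_id" & vc$var1=="(Intercept)" & is.na(vc$var2)],
    sep="\\n")
"""
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ll, s2, tau_f = (float(x) for x in out.stdout.split())
        assert small_fit.loglik >= ll - 1e-4
        assert small_fit.sigma2 == pytest.approx(s2, rel=1e-3)
        assert small_fit.varcomps["fish_id"]["tau"][0] == pytest.approx(
            tau_f, rel=1e-2, abs=1e-5)


class TestFitBehaviour:
    def test_deterministic(self, small_prepared, intrinsic_spec):
        table, _, _ = small_prepared
        a = oc.fit(intrinsic_spec, table)
        b = oc.fit(intrinsic_spec, table)
        assert a.loglik == b.loglik
        assert np.array_equal(a.theta, b.theta)

    def test_boundary_fit_flagged_singular(self):
        df = one_way_frame(30, 4, tau=0.0, sigma2=1.0, seed=21)
        res = oc.fit(oc.ModelSpec("y", (), (oc.RandomTerm("g"),), "REML"), df)
        assert res.singular

    def test_monotone_deviance_along_optimum(self, small_prepared,
                                             intrinsic_spec, small_fit):
        # the profiled deviance at the optimum is no worse than at the
        # standard starts
        table, _, _ = small_prepared
        work = small_fit._work
        for s in (0.3, 1.0):
            assert small_fit.deviance <= work.deviance(
                work.theta_start() * s, True) + 1e-9

    def test_duplicate_effect_rejected(self, small_prepared):
        table, _, _ = small_prepared
        with pytest.raises(SpecificationError):
            oc.fit(oc.ModelSpec(
                "log_width", (),
                (oc.RandomTerm("fish_id"), oc.RandomTerm("fish_id")),
                "REML"), table)
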