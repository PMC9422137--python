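"""Conditional-logistic estimation, AIC comparison, standardization, RSS."""

import math

import numpy as np
import pandas as pd
import pytest

from fenceline import model
from fenceline.model import (
    ModelSpec,
    all_model_specs,
    compare_models,
    conditional_loglik,
    crossing_contrast,
    expand_landcover,
    fit,
    log_rss,
    prepare_strata,
    range_vs_mean_curve,
    standardize_and_refit,
)

from .oracles import enumerate_loglik, simulate_clogit_strata


def _table_from_arrays(X, ids, case, columns):
    df = pd.DataFrame(X, columns=columns)
    df["stratum_id"] = ids
    df["case"] = np.asarray(case, dtype=int)
    return df


FEATURE_COLS = ["n_cross_FENCE", "n_cross_RNF"]


def _sim_table(beta, n_strata, seed, columns=None):
    columns = columns or FEATURE_COLS
    rng = np.random.default_rng(seed)
    X, ids, case = simulate_clogit_strata(beta, n_strata, rng)
    return _table_from_arrays(X, ids, case, columns)


class TestConditionalLoglik:
    def test_null_model_equal_probability(self):
        table = _sim_table([0.4, -0.3], 50, seed=1)
        prep = prepare_strata(table, FEATURE_COLS)
        ll = conditional_loglik(np.zeros(2), prep.design(FEATURE_COLS), prep.starts, prep.sizes, prep.case)
        assert ll == pytest.approx(-50 * math.log(6), abs=1e-12)

    def test_one_vs_one_closed_form(self):
        # single stratum, 1 used vs 1 available, covariate difference d
        d, beta = 1.7, -0.9
        table = pd.DataFrame(
            {
                "stratum_id": ["s", "s"],
                "case": [1, 0],
                "x": [d, 0.0],
            }
        )
        prep = prepare_strata(table, ["x"])
        ll = conditional_loglik(np.array([beta]), prep.design(["x"]), prep.starts, prep.sizes, prep.case)
        assert ll == pytest.approx(-math.log(1 + math.exp(-beta * d)), abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        X, ids, case = simulate_clogit_strata([-1.0, 0.5, 0.2], 10, rng)
        table = _table_from_arrays(X, ids, case, ["a", "b", "c"])
        prep = prepare_strata(table, ["a", "b", "c"])
        for _ in range(5):
            beta = rng.normal(size=3)
            got = conditional_loglik(beta, prep.design(["a", "b", "c"]), prep.starts, prep.sizes, prep.case)
            want = enumerate_loglik(beta, X, ids, case)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_within_stratum_constant_shift(self, rng):
        X, ids, case = simulate_clogit_strata([0.7], 30, rng, n_alt=6)
        shifts = np.repeat(rng.normal(size=30), 6)
        t1 = _table_from_arrays(X, ids, case, ["x"])
        t2 = _table_from_arrays(X + shifts[:, None], ids, case, ["x"])
        p1 = prepare_strata(t1, ["x"])
        p2 = prepare_strata(t2, ["x"])
        b = np.array([-0.4])
        ll1 = conditional_loglik(b, p1.design(["x"]), p1.starts, p1.sizes, p1.case)
        ll2 = conditional_loglik(b, p2.design(["x"]), p2.starts, p2.sizes, p2.case)
        assert ll1 == pytest.approx(ll2, abs=1e-9)


class TestFit:
    def test_null_spec_loglik_and_aic(self):
        table = _sim_table([0.0, 0.0], 40, seed=2)
        res = fit(ModelSpec(frozenset(), "crossing"), table)
        assert res.loglik == pytest.approx(-40 * math.log(6), abs=1e-12)
        assert res.aic == pytest.approx(-2 * res.loglik)
        assert res.k == 0 and res.converged

    def test_gradient_at_optimum(self):
        table = _sim_table([-1.0, 0.5], 500, seed=3)
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        res = fit(spec, table)
        prep = prepare_strata(table, res.covariates)
        _, grad, _ = model._loglik_grad_hess(
            res.beta.to_numpy(), prep.design(res.covariates), prep.starts, prep.sizes, prep.case
        )
        assert np.abs(grad).max() < 1e-6

    def test_parameter_recovery(self):
        """Known beta = (-1.5, -0.8): single fit within 3 SE; mean over 20
        replicates within +/-0.1 of the truth."""
        beta = np.array([-1.5, -0.8])
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        estimates = []
        for rep in range(20):
            table = _sim_table(beta, 2000, seed=100 + rep)
            res = fit(spec, table)
            assert res.converged
            est = res.beta.to_numpy()
            assert np.all(np.abs(est - beta) < 3 * res.se.to_numpy())
            estimates.append(est)
        mean_est = np.mean(estimates, axis=0)
        assert np.allclose(mean_est, beta, atol=0.1)

    def test_wald_ci_coverage(self):
        beta = np.array([-1.0, 0.6])
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        covered = np.zeros(2)
        n_rep = 40
        for rep in range(n_rep):
            table = _sim_table(beta, 400, seed=500 + rep)
            res = fit(spec, table)
            covered += np.abs(res.beta.to_numpy() - beta) <= 1.96 * res.se.to_numpy()
        assert (covered / n_rep >= 0.85).all()

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        table = _sim_table([-1.2, 0.7], 300, seed=4)
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        res = fit(spec, table)
        sm_fit = ConditionalLogit(
            table["case"].to_numpy(),
            table[FEATURE_COLS].to_numpy(),
            groups=table["stratum_id"].to_numpy(),
        ).fit(method="newton", tol=1e-10, disp=False)
        assert np.allclose(res.beta.to_numpy(), sm_fit.params, atol=1e-6)
        assert np.allclose(res.se.to_numpy(), sm_fit.bse, atol=1e-5)
        assert res.loglik == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_separation_detected(self):
        # a covariate that perfectly ranks used above available in every stratum
        rows = []
        for s in range(50):
            rows.append((f"s{s}", 1, 1.0))
            rows.extend((f"s{s}", 0, 0.0) for _ in range(5))
        table = pd.DataFrame(rows, columns=["stratum_id", "case", "n_cross_FENCE"])
        table["n_cross_FENCE"] = -table["n_cross_FENCE"]  # used always lower
        res = fit(ModelSpec(frozenset(["FENCE"]), "crossing"), table)
        assert res.separation and not res.converged


class TestCompareModels:
    @pytest.fixture(scope="class")
    def landcover_table(self):
        rng = np.random.default_rng(11)
        beta = np.array([-1.5, -1.0, -0.8, -0.6, 0.5, 0.1, -0.7])
        cols = [
            "n_cross_FENCE", "n_cross_RNF", "n_cross_R1F", "n_cross_R2F",
            "lc_NATIVE", "lc_PERENNIAL", "lc_OTHER",
        ]
        n_strata, n_alt = 600, 6
        X = np.zeros((n_strata * n_alt, 7))
        X[:, :4] = rng.poisson(0.4, size=(n_strata * n_alt, 4))
        lc = rng.integers(0, 4, size=n_strata * n_alt)
        for j in range(3):
            X[:, 4 + j] = lc == j + 1
        ids = np.repeat(np.arange(n_strata), n_alt)
        case = np.zeros(n_strata * n_alt, dtype=int)
        for s in range(n_strata):
            sl = slice(s * n_alt, (s + 1) * n_alt)
            eta = X[sl] @ beta
            p = np.exp(eta - eta.max())
            case[s * n_alt + rng.choice(n_alt, p=p / p.sum())] = 1
        df = pd.DataFrame(X, columns=cols)
        df["stratum_id"] = ids
        df["case"] = case
        df["landcover"] = np.array(["ANNUAL_CROP", "NATIVE", "PERENNIAL", "OTHER"])[lc]
        return df

    def test_all_32_models_ranked(self, landcover_table):
        comp = compare_models(landcover_table, "crossing")
        assert len(comp.fits) == 32
        assert comp.table["delta_aic"].iloc[0] == 0.0
        assert (comp.table["delta_aic"].diff().dropna() >= 0).all()

    def test_weights_sum_to_one(self, landcover_table):
        comp = compare_models(landcover_table, "crossing")
        assert comp.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_aic_identity(self, landcover_table):
        comp = compare_models(landcover_table, "crossing")
        for _, row in comp.table.iterrows():
            assert row["aic"] - (2 * row["k"] - 2 * row["loglik"]) == 0.0

    def test_strong_effects_select_full_model(self, landcover_table):
        comp = compare_models(landcover_table, "crossing")
        assert comp.table.iloc[0]["model"] == "FENCE+RNF+R1F+R2F+LANDCOVER"

    def test_spec_enumeration(self):
        specs = all_model_specs("proximity")
        assert len(specs) == 32
        assert sum(1 for s in specs if not s.blocks) == 1  # the null model
        labels = {s.label for s in specs}
        assert len(labels) == 32


class TestStandardization:
    def test_beta_scales_by_two_sd(self):
        table = _sim_table([-1.0, 0.5], 800, seed=6)
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        raw = fit(spec, table)
        recipe, std = standardize_and_refit(spec, table)
        for c in spec.covariates:
            sd = table[c].std(ddof=1)
            assert std.beta[c] / raw.beta[c] == pytest.approx(2 * sd, rel=1e-8)

    def test_sd_half_means_unchanged_beta(self, rng):
        x = rng.normal(scale=0.5, size=3000)
        x = (x - x.mean()) / x.std(ddof=1) * 0.5 + 1.0  # exact sd 0.5
        table = pd.DataFrame(
            {
                "stratum_id": np.repeat(np.arange(500), 6),
                "case": np.tile([1, 0, 0, 0, 0, 0], 500),
                "n_cross_FENCE": x,
            }
        )
        spec = ModelSpec(frozenset(["FENCE"]), "crossing")
        raw = fit(spec, table)
        recipe, std = standardize_and_refit(spec, table)
        assert recipe.scale["n_cross_FENCE"] == pytest.approx(1.0)
        assert std.beta["n_cross_FENCE"] == pytest.approx(raw.beta["n_cross_FENCE"], rel=1e-8)

    def test_recipe_round_trip(self):
        table = _sim_table([-1.0, 0.5], 100, seed=7)
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        recipe, _ = standardize_and_refit(spec, table)
        back = recipe.inverse(recipe.transform(table))
        for c in spec.covariates:
            assert np.allclose(back[c], table[c], atol=1e-10)

    def test_zero_sd_covariate_dropped(self):
        table = _sim_table([-1.0, 0.5], 100, seed=8)
        table["n_cross_RNF"] = 2.0
        spec = ModelSpec(frozenset(["FENCE", "RNF"]), "crossing")
        _, std = standardize_and_refit(spec, table)
        assert "n_cross_RNF" not in std.covariates

    def test_indicators_untouched(self, rng):
        table = _sim_table([-1.0], 300, seed=9, columns=["n_cross_FENCE"])
        table["landcover"] = rng.choice(["NATIVE", "ANNUAL_CROP"], size=len(table))
        table = expand_landcover(table)
        spec = ModelSpec(frozenset(["FENCE", "LANDCOVER"]), "crossing")
        recipe, _ = standardize_and_refit(spec, table)
        assert set(recipe.center) == {"n_cross_FENCE"}


class TestRSS:
    @pytest.fixture(scope="class")
    def fitted(self):
        table = _sim_table([-1.0, 0.5], 800, seed=10)
        return fit(ModelSpec(frozenset(["FENCE", "RNF"]), "crossing"), table)

    def test_identical_profiles_rss_one(self, fitted):
        x = {c: 0.3 for c in fitted.covariates}
        contrast = log_rss(fitted, x, x)
        assert contrast.log_rss == 0.0 and contrast.rss == 1.0

    def test_closed_form_unit_contrast(self):
        table = _sim_table([-1.0], 400, seed=12, columns=["n_cross_FENCE"])
        res = fit(ModelSpec(frozenset(["FENCE"]), "crossing"), table)
        c = crossing_contrast(res, "FENCE")
        assert c.rss == pytest.approx(math.exp(res.beta["n_cross_FENCE"]), abs=1e-12)

    def test_beta_minus_one_is_63_percent_decrease(self, fitted):
        c = log_rss(fitted, {"n_cross_FENCE": 1.0, "n_cross_RNF": 0.0},
                    {"n_cross_FENCE": 0.0, "n_cross_RNF": 0.0})
        # with beta exactly -1 this is e^-1; here verify the identity itself
        assert c.rss == pytest.approx(math.exp(fitted.beta["n_cross_FENCE"]), abs=1e-12)
        assert math.exp(-1.0) == pytest.approx(0.3679, abs=5e-5)

    def test_contrast_matches_finite_difference(self, fitted):
        """1 - exp(beta) equals a finite-difference evaluation of the fitted
        utility for a one-unit crossing contrast."""
        c = crossing_contrast(fitted, "FENCE")
        x1 = np.array([1.0, 0.0])
        x2 = np.array([0.0, 0.0])
        beta = fitted.beta.to_numpy()
        fd = (beta @ x1) - (beta @ x2)
        assert c.log_rss == pytest.approx(fd, abs=1e-10)

    def test_missing_covariate_raises(self, fitted):
        with pytest.raises(ValueError, match="missing"):
            log_rss(fitted, {"n_cross_FENCE": 1.0}, {"n_cross_FENCE": 0.0})

    def test_curve_monotone_for_single_covariate(self):
        table = _sim_table([-1.0], 400, seed=13, columns=["n_cross_FENCE"])
        res = fit(ModelSpec(frozenset(["FENCE"]), "crossing"), table)
        curve = range_vs_mean_curve(res, "n_cross_FENCE", np.linspace(0, 5, 11),
                                    {"n_cross_FENCE": 2.0})
        assert (np.diff(curve["rss"]) < 0).all()  # negative beta: decreasing

    def test_curve_equals_one_at_mean(self):
        table = _sim_table([-1.0], 400, seed=14, columns=["n_cross_FENCE"])
        res = fit(ModelSpec(frozenset(["FENCE"]), "crossing"), table)
        curve = range_vs_mean_curve(res, "n_cross_FENCE", np.array([2.0]),
                                    {"n_cross_FENCE": 2.0})
        assert curve["rss"].iloc[0] == 1.0
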