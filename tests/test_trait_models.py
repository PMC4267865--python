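import itertools
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from phyloinv import trait_models as tm


def make_design(n=200, seed=0, p_extra=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "invasive": rng.integers(0, 2, n),
            "xb": rng.integers(0, 2, n).astype(float),
            "xc": rng.standard_normal(n),
        }
    )
    for j in range(p_extra):
        df[f"z{j}"] = rng.standard_normal(n)
    return df


class TestTraitContrasts:
    @pytest.fixture
    def tables(self):
        species = pd.DataFrame(
            {
                "species": ["alien1", "nat1", "nat2"],
                "status": ["non-invasive alien", "native", "native"],
                "alien_group": ["neophyte", pd.NA, pd.NA],
                "invasive": [0, 0, 0],
                "ellenberg_L": [4, 4, 9],
                "ellenberg_F": [6, 5, 1],
                "ellenberg_N": [7, 5, 1],
                "ellenberg_R": [5, 5, 5],
                "ellenberg_S": [0, 2, 0],
                "log_height": [math.log(30), math.log(60), math.log(10)],
                "clonal": [1, 1, 0],
                "life_form": ["therophyte", "therophyte", "phanerophyte"],
            }
        )
        records = pd.DataFrame(
            [
                {
                    "species": "alien1",
                    "nearest_native": "nat1",
                    "pnnd": 12.5,
                    "invasive": 0,
                }
            ]
        )
        return species, records

    def test_native_minus_alien_convention(self, tables):
        species, records = tables
        design = tm.trait_contrasts(species, records)
        row = design.iloc[0]
        assert row["d_ellenberg_N"] == 5 - 7
        assert row["d_ellenberg_F"] == 5 - 6
        assert row["d_log_height"] == pytest.approx(math.log(60 / 30))
        assert design.attrs["difference"] == "native minus alien"

    def test_categorical_mismatch_codes(self, tables):
        species, records = tables
        design = tm.trait_contrasts(species, records)
        row = design.iloc[0]
        assert row["d_life_form"] == 0  # both therophytes
        assert row["d_clonal"] == 0
        species2 = species.copy()
        species2.loc[1, "life_form"] = "phanerophyte"
        species2.loc[1, "clonal"] = 0
        row2 = tm.trait_contrasts(species2, records).iloc[0]
        assert row2["d_life_form"] == 1
        assert row2["d_clonal"] == 1

    def test_identical_trait_vectors_give_zero_differences(self, tables):
        species, records = tables
        species.loc[1, species.columns[4:]] = species.loc[0, species.columns[4:]]
        species.loc[1, ["ellenberg_L", "ellenberg_F", "ellenberg_N",
                        "ellenberg_R", "ellenberg_S", "log_height",
                        "clonal", "life_form"]] = species.loc[
            0, ["ellenberg_L", "ellenberg_F", "ellenberg_N", "ellenberg_R",
                "ellenberg_S", "log_height", "clonal", "life_form"]
        ].values
        design = tm.trait_contrasts(species, records)
        diff_cols = [c for c in design.columns if c.startswith("d_")]
        assert (design[diff_cols].iloc[0] == 0).all()

    def test_missing_native_traits_counted(self, tables):
        species, records = tables
        species.loc[1, "ellenberg_N"] = np.nan
        design = tm.trait_contrasts(species, records)
        assert len(design) == 0
        assert design.attrs["n_excluded"] == 1


class TestBinomialGLM:
    def test_intercept_only_balanced_response(self):
        df = pd.DataFrame({"invasive": [0, 1] * 50})
        fit = tm.fit_binomial_glm(df, [])
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_binary_predictor_equals_log_odds_ratio(self):
        df = make_design(n=500, seed=1)
        fit = tm.fit_binomial_glm(df, ["xb"])
        y, xb = df["invasive"], df["xb"]
        a = ((y == 1) & (xb == 1)).sum()
        b = ((y == 0) & (xb == 1)).sum()
        c = ((y == 1) & (xb == 0)).sum()
        d = ((y == 0) & (xb == 0)).sum()
        assert fit.coef[1] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-8
        )

    def test_coefficient_recovery_within_two_se(self):
        rng = np.random.default_rng(2)
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        eta = 0.5 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"invasive": y, "x1": x1, "x2": x2})
        fit = tm.fit_binomial_glm(df, ["x1", "x2"])
        se = np.sqrt(np.diag(fit.cov))
        assert abs(fit.coef[1] - 0.5) < 2 * se[1]
        assert abs(fit.coef[2] + 0.5) < 2 * se[2]

    def test_aicc_formula(self):
        df = make_design(n=100, seed=3)
        fit = tm.fit_binomial_glm(df, ["xc"])
        k, n = fit.k, fit.n
        assert fit.aicc == pytest.approx(
            -2 * fit.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        )

    def test_separation_flagged(self):
        df = pd.DataFrame(
            {"invasive": [0] * 20 + [1] * 20,
             "xc": np.r_[np.zeros(20), np.ones(20)]}
        )
        fit = tm.fit_binomial_glm(df, ["xc"])
        assert fit.separation

    def test_one_class_response_rejected(self):
        df = pd.DataFrame({"invasive": np.zeros(30), "xc": np.arange(30.0)})
        with pytest.raises(ValueError, match="both classes"):
            tm.fit_binomial_glm(df, ["xc"])


class TestEnumerateCandidates:
    @pytest.mark.parametrize(
        "n_vars,max_size,expected",
        [(3, 5, 8), (6, 2, 22), (17, 5, 9402)],
    )
    def test_counts(self, n_vars, max_size, expected):
        variables = [f"v{i}" for i in range(n_vars)]
        cands = tm.enumerate_candidates(variables, max_size)
        assert len(cands) == expected
        assert cands[0] == ()  # intercept-only model included
        assert len(set(cands)) == len(cands)

    def test_deterministic_order(self):
        a = tm.enumerate_candidates(list("abcd"), 3)
        b = tm.enumerate_candidates(list("abcd"), 3)
        assert a == b


class TestModelAverage:
    def test_single_model_identity(self):
        df = make_design(n=300, seed=4)
        fit = tm.fit_binomial_glm(df, ["xb", "xc"])
        ma = tm.model_average([fit]).set_index("variable")
        for i, name in enumerate(fit.names[1:], start=1):
            assert ma.loc[name, "coefficient"] == pytest.approx(fit.coef[i])
            assert ma.loc[name, "adjusted_se"] == pytest.approx(
                math.sqrt(fit.cov[i, i])
            )
            assert ma.loc[name, "importance"] == pytest.approx(1.0)

    def test_equal_aicc_gives_half_weights_and_zero_substitution(self):
        df = make_design(n=300, seed=5)
        f1 = tm.fit_binomial_glm(df, ["xc"])
        f2 = tm.fit_binomial_glm(df, ["xc"])
        # identical model twice: equal weights by construction
        ma = tm.model_average([f1, f2])
        np.testing.assert_allclose(ma.attrs["weights"], [0.5, 0.5])
        # a variable present in only one of two equal-weight models gets
        # half its conditional coefficient under full averaging
        f3 = tm.fit_binomial_glm(df, [])
        f3 = tm.GLMFit(**{**f3.__dict__, "aicc": f1.aicc})  # force tie
        ma2 = tm.model_average([f1, f3]).set_index("variable")
        assert ma2.loc["xc", "coefficient"] == pytest.approx(
            f1.coef[1] / 2
        )
        assert ma2.loc["xc", "importance"] == pytest.approx(0.5)

    def test_full_averaging_shrinks_relative_to_conditional(self):
        df = make_design(n=400, seed=6, p_extra=3)
        variables = ["xb", "xc", "z0", "z1", "z2"]
        fits = [
            tm.fit_binomial_glm(df, c)
            for c in tm.enumerate_candidates(variables, 3)
        ]
        full = tm.model_average(fits, variables=variables).set_index("variable")
        cond = tm.model_average(
            fits, variables=variables, mode="conditional"
        ).set_index("variable")
        for v in ["z0", "z1", "z2"]:
            assert abs(full.loc[v, "coefficient"]) <= abs(
                cond.loc[v, "coefficient"]
            ) + 1e-12

    def test_weights_sum_to_one_and_importance_in_unit_interval(self):
        df = make_design(n=300, seed=7, p_extra=2)
        fits = [
            tm.fit_binomial_glm(df, c)
            for c in tm.enumerate_candidates(["xb", "xc", "z0", "z1"], 2)
        ]
        ma = tm.model_average(fits)
        assert ma.attrs["weights"].sum() == pytest.approx(1.0)
        assert ma["importance"].between(0, 1).all()

    def test_all_failed_fits_rejected(self):
        df = pd.DataFrame(
            {"invasive": [0] * 10 + [1] * 10,
             "xc": np.r_[np.zeros(10), np.ones(10)]}
        )
        fit = tm.fit_binomial_glm(df, ["xc"])
        with pytest.raises(ValueError, match="no successful fits"):
            with pytest.warns(UserWarning):
                tm.model_average([fit])


class TestCountryGroupLM:
    def test_identical_groups_t_zero(self):
        recs = pd.DataFrame(
            {
                "invasive": [1, 1, 1, 0, 0, 0],
                "pnnd": [10.0, 20.0, 30.0, 10.0, 20.0, 30.0],
                "mpd": [50.0, 60.0, 70.0, 50.0, 60.0, 70.0],
            }
        )
        out = tm.country_group_lm(recs).set_index("response")
        assert out.loc["pnnd", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["pnnd", "p"] == pytest.approx(1.0)

    def test_matches_pooled_t_formula(self):
        recs = pd.DataFrame(
            {
                "invasive": [1, 1, 1, 0, 0, 0],
                "pnnd": [12.0, 15.0, 11.0, 8.0, 9.0, 10.0],
                "mpd": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        out = tm.country_group_lm(recs).set_index("response")
        g1 = np.array([12.0, 15.0, 11.0])
        g0 = np.array([8.0, 9.0, 10.0])
        sp2 = ((g1.var(ddof=1) * 2) + (g0.var(ddof=1) * 2)) / 4
        t = (g1.mean() - g0.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert out.loc["pnnd", "t"] == pytest.approx(t)
        assert out.loc["pnnd", "df"] == 4

    def test_small_group_rejected(self):
        recs = pd.DataFrame(
            {"invasive": [1, 0, 0], "pnnd": [1.0, 2.0, 3.0],
             "mpd": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            tm.country_group_lm(recs)


def simulate_lmm_records(
    rng, n_species=60, squares=8, plots=2,
    v_species=100.0, v_square=25.0, v_resid=50.0,
    mu_inv=180.0, mu_non=200.0,
):
    rows = []
    for s in range(n_species):
        inv = int(s < n_species // 2)
        mu = mu_inv if inv else mu_non
        us = rng.normal(0, math.sqrt(v_species))
        for q in range(squares):
            uq = rng.normal(0, math.sqrt(v_square))
            for p in range(plots):
                rows.append(
                    {
                        "species": f"sp{s}",
                        "square": f"sq{s}_{q}",
                        "invasive": inv,
                        "pnnd": mu + us + uq + rng.normal(0, math.sqrt(v_resid)),
                    }
                )
    return pd.DataFrame(rows)


class TestNestedLMM:
    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(8)
        df = simulate_lmm_records(
            rng, n_species=40, squares=4, plots=2,
            v_species=0.0, v_square=0.0, v_resid=25.0,
        )
        res = tm.fit_nested_lmm(df, "pnnd")
        ols_inv = df.loc[df["invasive"] == 1, "pnnd"].mean()
        ols_non = df.loc[df["invasive"] == 0, "pnnd"].mean()
        assert res.mean_invasive == pytest.approx(ols_inv, abs=0.5)
        assert res.mean_noninvasive == pytest.approx(ols_non, abs=0.5)

    def test_group_means_recovered_on_balanced_design(self):
        rng = np.random.default_rng(9)
        df = simulate_lmm_records(rng, n_species=80, squares=6, plots=2)
        res = tm.fit_nested_lmm(df, "pnnd")
        assert res.converged
        assert res.mean_invasive == pytest.approx(180.0, abs=8)
        assert res.mean_noninvasive == pytest.approx(200.0, abs=8)
        assert res.var_species == pytest.approx(100.0, rel=0.6)
        assert res.var_residual == pytest.approx(50.0, rel=0.4)

    def test_matches_lme4_reml_on_small_dataset(self, tmp_path):
        # cross-check the REML fit against R's lme4 on identical data
        rng = np.random.default_rng(10)
        df = simulate_lmm_records(rng, n_species=30, squares=4, plots=2)
        csv = tmp_path / "lmm.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$grp <- factor(ifelse(d$invasive == 1, "invasive", "noninvasive"))
            m <- lmer(pnnd ~ 0 + grp + (1 | species/square), data = d, REML = TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(fe[["grpinvasive"]], fe[["grpnoninvasive"]],
                vc$vcov[vc$grp == "species"],
                vc$vcov[vc$grp == "square:species"],
                vc$vcov[vc$grp == "Residual"], sep="\\n")
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300,
        )
        assert out.returncode == 0, out.stderr
        r_inv, r_non, r_vsp, r_vsq, r_vres = map(float, out.stdout.split())
        res = tm.fit_nested_lmm(df, "pnnd")
        assert res.mean_invasive == pytest.approx(r_inv, rel=1e-3)
        assert res.mean_noninvasive == pytest.approx(r_non, rel=1e-3)
        assert res.var_species == pytest.approx(r_vsp, rel=0.05, abs=1.0)
        assert res.var_square_in_species == pytest.approx(r_vsq, rel=0.05, abs=1.0)
        assert res.var_residual == pytest.approx(r_vres, rel=0.02)


class TestWilcoxon:
    def test_complete_separation_exact_p(self):
        res = tm.wilcoxon_rank_sum([10, 11, 12], [1, 2, 3],
                                   alternative="greater")
        assert res.W == 9.0  # maximum rank-sum statistic for 3 vs 3
        assert res.p == pytest.approx(1 / 20)  # 1 of C(6,3) arrangements
        assert res.method == "exact"

    def test_identical_multisets_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = tm.wilcoxon_rank_sum(x, list(x))
        assert res.p > 0.9

    def test_matches_bruteforce_permutation_distribution(self):
        x = [3.1, 4.5, 2.2]
        y = [1.0, 2.9, 0.5, 1.7]
        res = tm.wilcoxon_rank_sum(x, y, alternative="greater")
        pooled = np.array(x + y)
        n1 = len(x)
        count = 0
        total = 0
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        w_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(7), n1):
            total += 1
            w = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            if w >= w_obs:
                count += 1
        assert res.p == pytest.approx(count / total)

    def test_nan_change_indices_ignored(self):
        res = tm.wilcoxon_rank_sum(
            [1.0, np.nan, 3.0], [0.5, 0.2, np.nan, 0.1]
        )
        assert res.n_invasive == 2 and res.n_noninvasive == 3
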