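import numpy as np
import pandas as pd
import pytest

from apedraw.stats import (
    AnalysisConfig,
    _benjamini_hochberg,
    chisq_main_colour,
    correlation_screen,
    kruskal_with_posthoc,
    pairwise_permutation_posthoc,
    pca_fit,
    permutation_lm,
    run_full_analysis,
    vif,
)


def factor_data(rng, n=600, loadings=(0.75, 0.75, 0.75)):
    """11 variables driven by 3 latent factors (6 + 2 + 3 variables),
    mirroring the filling / colour / shape block structure."""
    blocks = [6, 2, 3]
    f = rng.normal(size=(n, 3))
    cols = []
    for b, (k, lam) in enumerate(zip(blocks, loadings)):
        for _ in range(k):
            cols.append(lam * f[:, b] + np.sqrt(1 - lam**2) * rng.normal(size=n))
    return pd.DataFrame(np.column_stack(cols), columns=[f"v{i}" for i in range(11)])


class TestCorrelationScreen:
    def test_duplicated_column_flagged(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        rep = correlation_screen(df)
        assert ("a", "b", pytest.approx(1.0)) in [
            (a, b, pytest.approx(r, abs=1e-12)) for a, b, r in rep.flagged
        ]

    def test_independent_columns_not_flagged(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 6)), columns=list("abcdef"))
        assert correlation_screen(df).flagged == []

    def test_exact_threshold_not_flagged(self):
        # construct sample correlation exactly 0.8 from orthonormal parts
        n = 40
        x = np.zeros(n)
        x[: n // 2] = 1.0
        x = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = np.zeros(n)
        z[::2] = 1.0
        z = z - z.mean() - (z @ x) * x
        z /= np.linalg.norm(z)
        y = 0.8 * x + 0.6 * z
        df = pd.DataFrame({"a": x, "b": y, "c": np.arange(n, dtype=float)})
        rep = correlation_screen(df, threshold=0.8)
        assert df["a"].corr(df["b"]) == pytest.approx(0.8)
        assert all({p[0], p[1]} != {"a", "b"} for p in rep.flagged)

    def test_constant_column_reported_undefined(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        rep = correlation_screen(df)
        assert ("a", "b") in rep.undefined

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_screen(pd.DataFrame({"a": [1.0, 2.0]}))


class TestPCA:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x, "b": 2 * x + 5})
        model = pca_fit(df)
        np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert model.retained == 1

    def test_explained_percent_sums_to_100(self, rng):
        model = pca_fit(factor_data(rng))
        assert model.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_scores_are_projection_of_standardized_data(self, rng):
        df = factor_data(rng, n=200)
        model = pca_fit(df)
        z = (df.to_numpy() - model.mean) / model.std
        np.testing.assert_allclose(model.scores.to_numpy(), z @ model.components, atol=1e-8)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        df = factor_data(rng, n=300)
        model = pca_fit(df)
        z = (df.to_numpy() - df.to_numpy().mean(0)) / df.to_numpy().std(0, ddof=1)
        sk = SkPCA().fit(z)
        # eigenvalues of the correlation matrix = sklearn variances * (n-1)/n... use covariance of z with ddof=1
        np.testing.assert_allclose(model.eigenvalues, sk.explained_variance_, rtol=1e-8)
        np.testing.assert_allclose(
            np.abs(model.scores.to_numpy()),
            np.abs(sk.transform(z)[:, : model.scores.shape[1]]),
            atol=1e-6,
        )

    def test_three_planted_factors_recovered(self, rng):
        model = pca_fit(factor_data(rng))
        assert model.retained == 3
        # every variable loads |.| > 0.5 on its own block's dimension
        load = np.abs(model.loadings.to_numpy())
        blocks = [0] * 6 + [1] * 2 + [2] * 3
        dims = {b: np.argmax(load[[i for i, bb in enumerate(blocks) if bb == b]].sum(axis=0)) for b in range(3)}
        assert len(set(dims.values())) == 3
        for i, b in enumerate(blocks):
            assert load[i, dims[b]] > 0.5

    def test_zero_variance_variable_named(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "flat": np.full(50, 3.0)})
        with pytest.raises(ValueError, match="flat"):
            pca_fit(df)

    def test_fewer_rows_than_variables_warns(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 11)), columns=[f"v{i}" for i in range(11)])
        with pytest.warns(UserWarning, match="fewer rows"):
            pca_fit(df)

    def test_varimax_preserves_communalities(self, rng):
        df = factor_data(rng)
        plain = pca_fit(df, rotation="none")
        rot = pca_fit(df, rotation="varimax")
        np.testing.assert_allclose(
            (plain.loadings.to_numpy() ** 2).sum(axis=1),
            (rot.loadings.to_numpy() ** 2).sum(axis=1),
            atol=1e-8,
        )


class TestKruskal:
    def test_identical_groups_statistic_near_zero(self):
        v = np.concatenate([np.arange(20.0), np.arange(20.0)])
        g = np.array(["a"] * 20 + ["b"] * 20)
        res = kruskal_with_posthoc(v, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_shifted_groups_all_significant(self, rng):
        vals, gs = [], []
        for i, g in enumerate("abc"):
            vals.append(rng.normal(3.0 * i, 1.0, size=30))
            gs += [g] * 30
        res = kruskal_with_posthoc(np.concatenate(vals), np.array(gs))
        assert res.p_value < 1e-3
        for i, a in enumerate(res.groups):
            for b in res.groups[i + 1:]:
                assert res.pairwise_adj.loc[a, b] < 0.05
        assert len(set(res.letters.values())) == 3

    def test_five_groups_df_four(self, rng):
        v = rng.normal(size=100)
        g = np.repeat(list("abcde"), 20)
        assert kruskal_with_posthoc(v, g).df == 4

    def test_small_group_excluded_with_warning(self, rng):
        v = np.concatenate([rng.normal(size=20), rng.normal(size=20), [1.0]])
        g = np.array(["a"] * 20 + ["b"] * 20 + ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            res = kruskal_with_posthoc(v, g)
        assert res.groups == ["a", "b"]
        assert res.excluded == ["tiny"]

    def test_adjusted_p_at_least_raw(self, rng):
        v = rng.normal(size=90)
        g = np.repeat(list("abc"), 30)
        res = kruskal_with_posthoc(v, g)
        for i, a in enumerate(res.groups):
            for b in res.groups[i + 1:]:
                assert res.pairwise_adj.loc[a, b] >= res.pairwise_raw.loc[a, b] - 1e-12


class TestBenjaminiHochberg:
    def hand_bh(self, p):
        """Step-up oracle computed longhand."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * m / rank_from_top)
            adj[i] = val
            prev = val
        return adj

    @pytest.mark.parametrize(
        "p",
        [
            [0.01, 0.02, 0.03],
            [0.5],
            [0.04, 0.9, 0.002, 0.049, 0.05, 0.3],
            [0.2, 0.2, 0.2, 0.2],
        ],
    )
    def test_matches_hand_oracle(self, p):
        np.testing.assert_allclose(_benjamini_hochberg(np.array(p)), self.hand_bh(p), atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=25)
        adj = _benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def balanced_design(rng, n=120):
    seasons = np.tile(["winter", "spring", "summer", "autumn"], n // 4)
    periods = np.tile(np.arange(1, n // 8 + 1), 8)[:n].astype(float)
    return pd.Series(seasons[:n]), pd.Series(periods)


class TestPermutationLM:
    def test_p_floor_when_effect_overwhelms(self, rng):
        season, period = balanced_design(rng)
        y = 2.0 * period.to_numpy() + rng.normal(size=len(period)) * 0.1
        res = permutation_lm(y, season, period, B=199, seed=0)
        assert res.p_perm["period"] == pytest.approx(1.0 / 200)

    def test_p_in_valid_range(self, rng):
        season, period = balanced_design(rng)
        y = rng.normal(size=len(period))
        res = permutation_lm(y, season, period, B=99, seed=1)
        for p in res.p_perm.values():
            assert 1.0 / 100 <= p <= 1.0

    def test_deterministic_given_seed(self, rng):
        season, period = balanced_design(rng)
        y = rng.normal(size=len(period))
        r1 = permutation_lm(y, season, period, B=500, seed=42)
        r2 = permutation_lm(y, season, period, B=500, seed=42)
        assert r1.p_perm == r2.p_perm

    def test_seed_stability_at_large_B(self, rng):
        """Two seeds at B=10,000 agree to < 0.01 on every reported p."""
        season, period = balanced_design(rng)
        y = rng.normal(size=len(period)) + 0.25 * period.to_numpy() / period.max()
        r1 = permutation_lm(y, season, period, B=10_000, seed=1)
        r2 = permutation_lm(y, season, period, B=10_000, seed=2)
        for t in ("season", "period"):
            assert abs(r1.p_perm[t] - r2.p_perm[t]) < 0.01

    def test_f_statistic_matches_statsmodels_anova(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        season, period = balanced_design(rng)
        y = rng.normal(size=len(period)) + 0.3 * (season == "winter").to_numpy()
        res = permutation_lm(y, season, period, B=9, seed=0)
        df = pd.DataFrame({"y": y, "season": season, "period": period})
        fit = smf.ols("y ~ C(season) + period", data=df).fit()
        tab = anova_lm(fit, typ=2)
        assert res.f_observed["season"] == pytest.approx(tab.loc["C(season)", "F"], rel=1e-8)
        assert res.f_observed["period"] == pytest.approx(tab.loc["period", "F"], rel=1e-8)

    def test_rank_deficient_design_names_term(self, rng):
        season = pd.Series(["winter"] * 40)   # constant factor aliases intercept
        period = pd.Series(np.arange(40, dtype=float))
        y = rng.normal(size=40)
        with pytest.raises(ValueError, match="rank|alias"):
            permutation_lm(y, season, period, B=9)

    def test_missing_values_rejected(self):
        season = pd.Series(["winter", "spring"] * 10)
        period = pd.Series(np.arange(20, dtype=float))
        y = np.full(20, np.nan)
        with pytest.raises(ValueError):
            permutation_lm(y, season, period, B=9)


class TestVIF:
    def test_orthogonal_predictors_unity(self, rng):
        n = 400
        df = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2), "b": np.repeat([1.0, -1.0], n // 2)})
        out = vif(df)
        assert out["a"] == pytest.approx(1.0, abs=1e-9)
        assert out["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_infinite(self, rng):
        x = rng.normal(size=100)
        out = vif(pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_balanced_season_period_below_1_1(self, rng):
        season, period = balanced_design(rng, n=160)
        res = permutation_lm(rng.normal(size=160), season, period, B=9, seed=0)
        assert res.vif["season"] < 1.1
        assert res.vif["period"] < 1.1
        assert all(v >= 1.0 - 1e-9 for v in res.vif.values())


class TestPairwisePermutation:
    def test_identical_groups_not_significant(self, rng):
        y = np.tile(np.arange(20.0), 3)
        g = np.repeat(list("abc"), 20)
        adj = pairwise_permutation_posthoc(y, g, B=299, seed=0)
        for a in "abc":
            for b in "abc":
                if a < b:
                    assert adj.loc[a, b] > 0.5

    def test_single_shifted_group_detected(self, rng):
        base = rng.normal(size=25)  # a, b, c share the same sample: exact null
        y = np.concatenate([base, base, base, rng.normal(4.0, 1.0, size=25)])
        g = np.repeat(list("abcd"), 25)
        adj = pairwise_permutation_posthoc(y, g, B=499, seed=1)
        for a in "abc":
            assert adj.loc[a, "d"] < 0.05
        for a, b in (("a", "b"), ("a", "c"), ("b", "c")):
            assert adj.loc[a, b] > 0.05

    def test_winter_deficit_pattern(self, rng):
        """A -1 SD winter shift flags exactly the winter pairs."""
        seasons = np.repeat(["winter", "spring", "summer", "autumn"], 40)
        y = rng.normal(size=160) - (seasons == "winter") * 1.0
        adj = pairwise_permutation_posthoc(y, seasons, B=499, seed=2)
        for s in ("spring", "summer", "autumn"):
            assert adj.loc["winter", s] < 0.05


class TestChiSquare:
    def test_uniform_counts_statistic_zero(self):
        colours = pd.Series([0, 1, 2, 3] * 10)
        groups = pd.Series(["g"] * 40)
        (res,) = chisq_main_colour(colours, groups)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 3

    def test_one_hot_profile(self):
        colours = pd.Series([5] * 40 + [1, 2, 3])
        groups = pd.Series(["mono"] * 40 + ["other"] * 3)
        res = {r.group: r for r in chisq_main_colour(colours, groups)}
        assert res["mono"].modal_colour == "5"
        assert res["mono"].modal_share == pytest.approx(1.0)
        assert res["mono"].p_value < 1e-10

    def test_dominant_colour_share_recovered(self, rng):
        cats = list(range(12))
        p = np.full(12, 0.6 / 11)
        p[0] = 0.4
        draws = rng.choice(cats, size=200, p=p)
        res = chisq_main_colour(pd.Series(draws), pd.Series(["g"] * 200))
        assert res[0].modal_colour == "0"
        assert res[0].modal_share == pytest.approx(0.4, abs=0.1)
        assert res[0].p_value < 0.001

    def test_small_expected_flagged(self):
        colours = pd.Series([0, 1, 2, 0])
        (res,) = chisq_main_colour(colours, pd.Series(["g"] * 4))
        assert res.small_expected


class TestRunFullAnalysis:
    def make_metrics(self, rng, n_per=40, individuals=("A", "B")):
        rows = []
        for ind_i, ind in enumerate(individuals):
            for k in range(n_per):
                period = k % 19 + 1
                season = ["winter", "spring", "summer", "autumn"][k % 4]
                base = rng.normal(size=11) + ind_i * 1.5
                rows.append(
                    dict(
                        drawing_id=f"{ind}{k}", individual=ind, season=season, period=period,
                        coverage_rate=abs(base[0]) / 4, overlap_rate=abs(base[1]) * 10,
                        n_colours=int(abs(base[2]) * 2) + 1, fan=int(abs(base[3])),
                        circle=int(abs(base[4])), triangle=int(abs(base[5])),
                        loop=int(abs(base[6])), colour_mean=0.8 + base[7] / 50,
                        colour_sd=0.1 + abs(base[8]) / 50, dist_centre_mm=abs(base[9]) * 20,
                        solid_colour_rate=abs(base[10]) / 20, main_colour=int(rng.integers(0, 4)),
                    )
                )
        return pd.DataFrame(rows)

    def test_missing_columns_named(self, rng):
        df = self.make_metrics(rng).drop(columns=["overlap_rate", "loop"])
        with pytest.raises(ValueError, match="overlap_rate"):
            run_full_analysis(df, AnalysisConfig(B=9))

    def test_single_individual_skips_inter_arm(self, rng):
        df = self.make_metrics(rng, individuals=("A",))
        rep = run_full_analysis(df, AnalysisConfig(B=19, seed=0))
        assert rep.pca_inter is None
        assert any("skipped" in line for line in rep.log)
        assert rep.pca_long is not None

    def test_report_structure_and_determinism(self, rng, tmp_path):
        df = self.make_metrics(rng)
        cfg = AnalysisConfig(B=49, seed=7)
        rep1 = run_full_analysis(df, cfg)
        rep1.write(tmp_path / "r1")
        rep2 = run_full_analysis(df, cfg)
        rep2.write(tmp_path / "r2")
        for name in ("group_tests.json", "perm_lm.json", "colour_tests.json",
                     "pca_loadings.csv", "pca_scores.csv", "run_log.txt"):
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()
        assert rep1.pca_inter.variables == [
            "coverage_rate", "overlap_rate", "n_colours", "fan", "circle", "triangle",
            "loop", "colour_mean", "colour_sd", "dist_centre_mm", "solid_colour_rate",
        ]
        assert len(rep1.pca_inter.variables) == 11
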