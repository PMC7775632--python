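"""Statistical kernel: rank tests, FDR, rmANOVA, correlations, T2, PCA score."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import steadyfield.stats as st


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_samples_give_half_of_pairs(self):
        res = st.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 9 / 2

    def test_exact_p_matches_permutation_enumeration_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(0.8, 1.0, size=5)
        res = st.mann_whitney_u(a, b)
        # oracle: enumerate every assignment of the pooled values to groups
        pooled = np.concatenate([a, b])
        mu = 25 / 2

        def u_of(idx):
            aa = pooled[list(idx)]
            bb = np.delete(pooled, list(idx))
            return sum(
                1.0 if x > y else 0.5 if x == y else 0.0 for x in aa for y in bb
            )

        obs = abs(u_of(range(5)) - mu)
        devs = [abs(u_of(c) - mu) for c in itertools.combinations(range(10), 5)]
        oracle_p = np.mean([d >= obs - 1e-12 for d in devs])
        assert res.p_raw == pytest.approx(oracle_p, abs=1e-10)

    def test_exact_p_matches_scipy_without_ties(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        res = st.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert res.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_p_matches_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.4, 1.0, size=25)
        res = st.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariance_to_monotone_transform(self, rng):
        a = rng.normal(size=12) + 3.0
        b = rng.normal(size=15) + 3.0
        r1 = st.mann_whitney_u(a, b)
        r2 = st.mann_whitney_u(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic and r1.p_raw == r2.p_raw

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences_give_t_zero(self):
        res = st.wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        assert res.statistic == 0.0

    def test_antisymmetric_differences_give_z_near_zero(self):
        d = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0]
        res = st.wilcoxon_signed_rank(d)
        assert abs(res.extras["z"]) < 1e-9

    def test_exact_p_matches_sign_flip_enumeration_oracle(self, rng):
        d = rng.normal(0.6, 1.0, size=8)
        res = st.wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        total = ranks.sum()
        t_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = sum(
            min(sum(r for r, s in zip(ranks, signs) if s), total - sum(r for r, s in zip(ranks, signs) if s))
            <= t_obs + 1e-12
            for signs in itertools.product((0, 1), repeat=8)
        )
        assert res.p_raw == pytest.approx(count / 256, abs=1e-12)

    def test_exact_p_matches_scipy(self, rng):
        d = rng.normal(0.5, 1.0, size=8)
        res = st.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, mode="exact")
        assert res.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped_and_all_zero_marked(self):
        res = st.wilcoxon_signed_rank([0.0] * 6)
        assert math.isnan(res.statistic)
        with pytest.raises(ValueError, match="5 nonzero"):
            st.wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0])


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

class TestFDR:
    def test_single_p_rejected_iff_below_q(self):
        assert st.fdr_bh([0.04], 0.05)[0][0]
        assert not st.fdr_bh([0.06], 0.05)[0][0]

    @pytest.mark.parametrize("p0, expect", [(0.04, True), (0.051, False)])
    def test_equal_p_family_all_or_nothing(self, p0, expect):
        mask, _ = st.fdr_bh([p0] * 20, 0.05)
        assert mask.all() == expect and mask.any() == expect

    def test_rejections_match_definition_level_scan(self, rng):
        p = rng.uniform(size=20) ** 2
        mask, adj = st.fdr_bh(p, 0.05)
        # oracle: largest k with p_(k) <= k q / m; reject the k smallest
        order = np.argsort(p)
        ks = [k for k in range(1, 21) if p[order[k - 1]] <= k * 0.05 / 20]
        expected = np.zeros(20, dtype=bool)
        if ks:
            expected[order[: max(ks)]] = True
        np.testing.assert_array_equal(mask, expected)
        assert np.all(adj >= p - 1e-15)

    def test_bonferroni_dominates_bh(self, rng):
        p = rng.uniform(size=15)
        _, adj_bh = st.fdr_bh(p)
        _, adj_bon, _ = st.bonferroni(p)
        assert np.all(adj_bon >= adj_bh - 1e-12)


class TestBonferroni:
    def test_family_of_eight_threshold(self):
        _, _, thr = st.bonferroni([0.01], family_size=8)
        assert thr == pytest.approx(0.00625)
        assert round(thr, 3) == 0.006

    def test_single_test_unchanged_and_capping(self):
        _, adj, _ = st.bonferroni([0.3], family_size=1)
        assert adj[0] == 0.3
        _, adj, _ = st.bonferroni([0.3], family_size=5)
        assert adj[0] == 1.0


# ---------------------------------------------------------------------------
# rmANOVA
# ---------------------------------------------------------------------------

def _cs_table(rng, n_subj=10, levels=4):
    """Cell table whose orthonormal-contrast sample covariance is spherical."""
    z = rng.standard_normal((n_subj, levels - 1))
    z -= z.mean(axis=0)
    # whiten empirically so the contrast covariance is exactly the identity
    cov = np.cov(z.T, ddof=1)
    z = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    c = st._orthonormal_contrasts(levels)
    return z @ c + rng.standard_normal((n_subj, 1))


class TestRmAnova:
    def test_two_level_within_equals_squared_paired_t(self, rng):
        y = rng.standard_normal((12, 2))
        table = st.rm_anova_gg(y, np.array(["A"] * 12), within_names=["cond"])
        t, p = sps.ttest_rel(y[:, 0], y[:, 1])
        row = table[table["effect"] == "cond"].iloc[0]
        assert row["F"] == pytest.approx(t**2, rel=1e-9)
        assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_compound_symmetry_gives_epsilon_one(self, rng):
        y = _cs_table(rng)
        table = st.rm_anova_gg(y, np.array(["A"] * 10), within_names=["w"])
        eps = table.loc[table["effect"] == "w", "gg_epsilon"].iloc[0]
        assert eps == pytest.approx(1.0, abs=1e-9)

    def test_sums_of_squares_match_cell_means_oracle(self, rng):
        """2-group x (2 x 3) within design vs a direct textbook decomposition."""
        n = 4
        y = rng.integers(0, 10, size=(2 * n, 2, 3)).astype(float)
        groups = np.array(["A"] * n + ["B"] * n)
        table = st.rm_anova_gg(y, groups, within_names=["a", "b"])

        # oracle: explicit mean-based formulas
        grand = y.mean()
        subj_means = y.mean(axis=(1, 2))
        group_means = {g: y[groups == g].mean() for g in "AB"}
        ss_group = sum(
            (groups == g).sum() * 6 * (group_means[g] - grand) ** 2 for g in "AB"
        )
        ss_subj = 6 * ((subj_means - np.repeat([group_means["A"], group_means["B"]], n)) ** 2).sum()
        a_means = y.mean(axis=(0, 2))
        ss_a = 2 * n * 3 * ((a_means - grand) ** 2).sum()
        b_means = y.mean(axis=(0, 1))
        ss_b = 2 * n * 2 * ((b_means - grand) ** 2).sum()
        ab_means = y.mean(axis=0)
        ss_ab = 2 * n * (
            (ab_means - a_means[:, None] - b_means[None, :] + grand) ** 2
        ).sum()

        def row(name):
            return table.loc[table["effect"] == name].iloc[0]

        assert row("group")["SS"] == pytest.approx(ss_group, rel=1e-10)
        assert row("a")["SS"] == pytest.approx(ss_a, rel=1e-10)
        assert row("b")["SS"] == pytest.approx(ss_b, rel=1e-10)
        assert row("a x b")["SS"] == pytest.approx(ss_ab, rel=1e-10)
        assert table.attrs["ss_accounted"] == pytest.approx(
            table.attrs["ss_total"], rel=1e-10
        )
        assert row("group")["SS_error"] == pytest.approx(ss_subj, rel=1e-10)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        n, levels = 9, 4
        y = rng.standard_normal((2 * n, levels)) + rng.standard_normal((2 * n, 1))
        groups = np.array(["A"] * n + ["B"] * n)
        table = st.rm_anova_gg(y, groups, within_names=["time"])
        rows = [
            dict(subj=i, group=groups[i], time=l, y=y[i, l])
            for i in range(2 * n)
            for l in range(levels)
        ]
        ref = pg.mixed_anova(
            pd.DataFrame(rows), dv="y", within="time", subject="subj",
            between="group", correction=True,
        )
        ours = {r["effect"]: r for _, r in table.iterrows()}
        refd = {r["Source"]: r for _, r in ref.iterrows()}
        assert ours["group"]["F"] == pytest.approx(refd["group"]["F"], rel=1e-9)
        assert ours["time"]["F"] == pytest.approx(refd["time"]["F"], rel=1e-9)
        assert ours["time x group"]["F"] == pytest.approx(refd["Interaction"]["F"], rel=1e-9)
        assert ours["time"]["partial_eta_squared"] == pytest.approx(refd["time"]["np2"], rel=1e-9)

    def test_missing_cells_rejected(self):
        y = np.ones((4, 2, 2))
        y[0, 1, 1] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            st.rm_anova_gg(y, np.array(["A", "A", "B", "B"]))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

class TestCorrelations:
    def test_linear_relation_gives_pearson_one(self):
        x = np.arange(10.0)
        res = st.correlation(x, 2 * x + 1, "pearson")
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_nonlinearity_ranks_perfectly(self):
        x = np.linspace(0, 3, 12)
        sp = st.correlation(x, np.exp(x), "spearman")
        pe = st.correlation(x, np.exp(x), "pearson")
        assert sp.statistic == pytest.approx(1.0)
        assert pe.statistic < 1.0

    def test_spearman_equals_pearson_on_midranks(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = st.correlation(x, y, "spearman")
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_residualization_removes_linear_trend(self, rng):
        age = rng.uniform(7, 13, 40)
        x = 2.0 * age + rng.normal(0, 0.5, 40)
        y = -1.5 * age + rng.normal(0, 0.5, 40)
        plain = st.correlation(x, y, "pearson")
        detrended = st.correlation(x, y, "pearson", residualize_on=age)
        assert plain.statistic < -0.8                 # driven by shared trend
        assert abs(detrended.statistic) < 0.5

    def test_zero_variance_marked_undefined(self):
        res = st.correlation([1.0] * 6, [1, 2, 3, 4, 5, 6], "pearson")
        assert math.isnan(res.statistic)

    def test_partial_correlation_matches_precision_matrix_identity(self, rng):
        data = rng.standard_normal((40, 3))
        data[:, 1] += 0.6 * data[:, 2]
        data[:, 0] += 0.4 * data[:, 2] + 0.3 * data[:, 1]
        res = st.partial_correlation(data[:, 0], data[:, 1], data[:, 2][None, :])
        prec = np.linalg.inv(np.corrcoef(data.T))
        oracle = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_partial_correlation_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.standard_normal((25, 3)), columns=["x", "y", "c"])
        res = st.partial_correlation(df["x"], df["y"], df[["c"]].to_numpy().T)
        ref = pg.partial_corr(df, x="x", y="y", covar="c")
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_raw == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_control_identical_to_outcome_marked_undefined(self, rng):
        c = rng.normal(size=10)
        res = st.partial_correlation(rng.normal(size=10), c, c[None, :])
        assert math.isnan(res.statistic)

    def test_collinear_controls_rejected(self, rng):
        c1 = rng.normal(size=12)
        controls = np.vstack([c1, 2 * c1])
        with pytest.raises(ValueError, match="collinear"):
            st.partial_correlation(rng.normal(size=12), rng.normal(size=12), controls)


# ---------------------------------------------------------------------------
# Hotelling T2 and effect sizes
# ---------------------------------------------------------------------------

class TestHotelling:
    def test_identical_samples_give_zero(self, rng):
        x = rng.standard_normal((6, 3))
        res = st.hotelling_t2(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_one_dimensional_case_reduces_to_squared_t(self, rng):
        x = rng.normal(size=(8, 1))
        y = rng.normal(0.7, 1.0, size=(10, 1))
        res = st.hotelling_t2(x, y)
        t, p = sps.ttest_ind(x[:, 0], y[:, 0])
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_raw == pytest.approx(p, rel=1e-10)

    def test_matches_pooled_covariance_quadratic_form_oracle(self, rng):
        x = rng.standard_normal((5, 3))
        y = rng.standard_normal((5, 3)) + [0.5, -0.2, 0.1]
        res = st.hotelling_t2(x, y)
        d = x.mean(axis=0) - y.mean(axis=0)
        s = (4 * np.cov(x.T, ddof=1) + 4 * np.cov(y.T, ddof=1)) / 8
        oracle = (5 * 5 / 10) * d @ np.linalg.inv(s) @ d
        assert res.statistic == pytest.approx(oracle, rel=1e-10)

    def test_singular_covariance_names_collinear_axes(self, rng):
        x = rng.standard_normal((6, 1))
        xx = np.hstack([x, 2 * x, rng.standard_normal((6, 1))])
        yy = np.hstack([x + 0.1, 2 * (x + 0.1), rng.standard_normal((6, 1))])
        with pytest.raises(ValueError, match="collinear"):
            st.hotelling_t2(xx, yy, axis_names=["X", "Y", "Z"])


class TestEffectSizes:
    def test_equal_means_give_zero_d(self):
        assert st.cohens_d([1, 2, 3], [3, 2, 1]) == 0.0

    def test_unit_shift_unit_sd_gives_one(self):
        # sample means 1 and 0, both sample SDs exactly 1
        assert st.cohens_d([0.0, 1.0, 2.0], [-1.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_matches_pooled_sd_formula_oracle(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(1.0, 2.0, size=10)
        pooled = math.sqrt((a.var(ddof=1) * 9 + b.var(ddof=1) * 9) / 18)
        assert st.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_partial_eta_squared_formula(self):
        assert st.partial_eta_squared(3.0, 9.0) == 0.25


# ---------------------------------------------------------------------------
# PCA Autism Score
# ---------------------------------------------------------------------------

def _scales_frame(raw):
    return pd.DataFrame(raw, columns=["srs", "scq", "aq"])


class TestAutismScore:
    def test_perfectly_correlated_scales(self, rng):
        base = rng.normal(size=12)
        tab = _scales_frame(np.column_stack([base, 2 * base + 1, -0.5 + 3 * base]))
        model, scores = st.autism_score_pca(tab)
        assert model.variance_explained == pytest.approx(1.0)
        assert abs(np.corrcoef(scores, base)[0, 1]) == pytest.approx(1.0)

    def test_higher_severity_gives_higher_score(self, rng):
        raw = rng.normal(50, 10, size=(20, 3)) + rng.normal(0, 5, size=(20, 1))
        tab = _scales_frame(raw)
        model, scores = st.autism_score_pca(tab)
        # totals across scales and scores must be positively associated
        assert np.corrcoef(raw.sum(axis=1), scores)[0, 1] > 0
        assert np.linalg.norm(model.loadings) == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        raw = rng.normal(size=(6, 3)) @ np.array([[1, 0.5, 0.2], [0, 1, 0.4], [0, 0, 1]])
        tab = _scales_frame(raw)
        model, scores = st.autism_score_pca(tab)
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        vals, vecs = np.linalg.eigh(np.cov(z.T, ddof=1))
        v = vecs[:, -1] * np.sign(vecs[:, -1].mean())
        np.testing.assert_allclose(scores.to_numpy(), z @ v, atol=1e-10)
        assert model.variance_explained == pytest.approx(vals[-1] / vals.sum())

    def test_missing_imputed_with_mean_of_available_z(self, rng):
        raw = rng.normal(50, 10, size=(8, 3)).astype(float)
        tab = _scales_frame(raw)
        tab.loc[0, "aq"] = np.nan
        model, scores = st.autism_score_pca(tab)
        z = (tab[["srs", "scq"]].iloc[0] - np.nanmean(tab[["srs", "scq"]], axis=0))
        # score of subject 0 is finite and consistent with the imputation rule
        assert np.isfinite(scores.iloc[0])
        means = np.nanmean(tab[model.scale_names], axis=0)
        sds = np.nanstd(tab[model.scale_names], axis=0, ddof=1)
        z0 = (tab[model.scale_names].iloc[0].to_numpy() - means) / sds
        z0[2] = np.nanmean(z0[:2])
        assert scores.iloc[0] == pytest.approx(z0 @ model.loadings)

    def test_subject_with_no_scales_dropped(self, rng):
        raw = rng.normal(50, 10, size=(6, 3))
        tab = _scales_frame(raw)
        tab.loc[2, :] = np.nan
        _, scores = st.autism_score_pca(tab)
        assert 2 not in scores.index
        assert len(scores) == 5

    def test_mean_score_near_zero_over_fitting_group(self, rng):
        raw = rng.normal(50, 12, size=(30, 3))
        _, scores = st.autism_score_pca(_scales_frame(raw))
        assert abs(scores.mean()) < 0.15


# ---------------------------------------------------------------------------
# Type-I calibration of the kernel tests
# ---------------------------------------------------------------------------

class TestTypeICalibration:
    N_SIMS = 2000

    def test_rank_and_correlation_tests_hold_nominal_level(self):
        rng = np.random.default_rng(314159)
        rejections = {"mw": 0, "wilcoxon": 0, "pearson": 0}
        for _ in range(self.N_SIMS):
            a = rng.standard_normal(35)
            b = rng.standard_normal(35)
            if st.mann_whitney_u(a, b).p_raw < 0.05:
                rejections["mw"] += 1
            if st.wilcoxon_signed_rank(a - b).p_raw < 0.05:
                rejections["wilcoxon"] += 1
            if st.correlation(a, b, "pearson").p_raw < 0.05:
                rejections["pearson"] += 1
        for name, count in rejections.items():
            rate = count / self.N_SIMS
            assert 0.035 <= rate <= 0.065, f"{name} rejects at {rate:.3f}"
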