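import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hipporad import registry
from hipporad.stats import (
    AdjustedTable,
    adjust_covariates,
    anova_screen,
    posthoc_pairwise,
    spearman_rho_p,
    spearman_screen,
    summarize_multiregion,
)

import oracles


def _covariates(groups, rng):
    n = len(groups)
    return pd.DataFrame(
        {
            "group": groups,
            "age": rng.normal(70, 7, n),
            "gender": rng.choice(["M", "F"], n),
            "mmse": rng.normal(25, 4, n),
        }
    )


def _adjusted_from_matrix(X, groups, rng=None, columns=None):
    """Wrap a plain matrix as an AdjustedTable (screening input) without
    running the OLS step, for null-calibration style tests."""
    rng = rng or np.random.default_rng(0)
    cov = _covariates(groups, rng)
    cols = columns if columns is not None else [f"f{i}" for i in range(X.shape[1])]
    return AdjustedTable(
        features=pd.DataFrame(X, columns=cols),
        coefficients=pd.DataFrame(),
        groups=pd.Series(groups),
        covariates=cov,
    )


class TestAdjustCovariates:
    def test_perfect_linear_fit_zero_residual_variance(self, rng):
        cov = _covariates(["NC"] * 50, rng)
        feature = 3.0 * cov["age"].to_numpy() + 1.0
        features = pd.DataFrame({"f": feature})
        adj = adjust_covariates(features, cov)
        assert adj.features["f"].var() == pytest.approx(0.0, abs=1e-18)
        assert adj.coefficients.loc["age", "f"] == pytest.approx(3.0)

    def test_ols_matches_normal_equations(self, rng):
        cov = _covariates(["NC"] * 40, rng)
        y = rng.normal(size=40)
        adj = adjust_covariates(pd.DataFrame({"f": y}), cov)
        X = np.column_stack(
            [np.ones(40), cov["age"], (cov["gender"] == "F").astype(float)]
        )
        beta = oracles.ols_normal_equations(X, y)
        np.testing.assert_allclose(adj.coefficients["f"].to_numpy(), beta, rtol=1e-8)

    def test_independent_covariates_slopes_near_zero(self, rng):
        n = 200
        cov = _covariates(["NC"] * n, rng)
        Y = pd.DataFrame(rng.normal(size=(n, 20)))
        Y.columns = [f"f{i}" for i in range(20)]
        adj = adjust_covariates(Y, cov)
        # slope standard error for unit-variance noise
        age = cov["age"].to_numpy()
        se = 1.0 / np.sqrt(((age - age.mean()) ** 2).sum())
        assert (np.abs(adj.coefficients.loc["age"]) < 3 * se).mean() > 0.9

    def test_adjustment_idempotent(self, rng):
        cov = _covariates(["NC", "aMCI", "AD"] * 10, rng)
        Y = pd.DataFrame(rng.normal(size=(30, 5)), columns=[f"f{i}" for i in range(5)])
        once = adjust_covariates(Y, cov)
        twice = adjust_covariates(once.features, cov)
        np.testing.assert_allclose(
            once.features.to_numpy(), twice.features.to_numpy(), atol=1e-10
        )

    def test_residuals_orthogonal_to_covariates(self, rng):
        cov = _covariates(["NC"] * 60, rng)
        Y = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"f{i}" for i in range(10)])
        adj = adjust_covariates(Y, cov)
        resid = adj.features.to_numpy() - adj.features.to_numpy().mean(axis=0)
        age = cov["age"].to_numpy() - cov["age"].mean()
        assert np.abs(age @ resid).max() < 1e-8 * np.abs(age).sum()

    def test_constant_covariate_dropped_with_warning(self, rng):
        cov = _covariates(["NC"] * 20, rng)
        cov["gender"] = "M"
        Y = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        with pytest.warns(UserWarning, match="gender"):
            adj = adjust_covariates(Y, cov)
        assert "gender" not in adj.coefficients.index


class TestAnovaScreen:
    def test_toy_three_group_f_matches_oracle(self):
        g1, g2, g3 = np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([5.0, 6, 7])
        X = np.concatenate([g1, g2, g3])[:, None]
        groups = ["NC"] * 3 + ["aMCI"] * 3 + ["AD"] * 3
        screen = anova_screen(_adjusted_from_matrix(X, groups))
        assert screen.table["F"].iloc[0] == pytest.approx(oracles.oneway_f([g1, g2, g3]))
        f_sp, p_sp = sps.f_oneway(g1, g2, g3)
        assert screen.table["F"].iloc[0] == pytest.approx(f_sp)
        assert screen.table["p_anova"].iloc[0] == pytest.approx(p_sp)

    def test_identical_groups_f_zero_p_one(self):
        X = np.ones((9, 2))
        groups = ["NC"] * 3 + ["aMCI"] * 3 + ["AD"] * 3
        screen = anova_screen(_adjusted_from_matrix(X, groups))
        assert (screen.table["F"] == 0).all()
        assert (screen.table["p_anova"] == 1).all()

    def test_null_flag_rate_within_bonferroni_expectation(self):
        """Under the global null the family-wise flag count should average
        about alpha per 1692-feature family (Bonferroni calibration)."""
        rng = np.random.default_rng(42)
        groups = ["NC"] * 10 + ["aMCI"] * 10 + ["AD"] * 10
        total_flags = 0
        reps = 20
        for _ in range(reps):
            X = rng.normal(size=(30, 1692))
            screen = anova_screen(_adjusted_from_matrix(X, groups), alpha=0.01, n_tests=1692)
            total_flags += int(screen.table["sig_anova"].sum())
        # E[flags] = alpha = 0.01 per replicate; allow generous Poisson slack
        assert total_flags <= 4

    def test_row_and_column_order_invariance(self, rng):
        X = rng.normal(size=(24, 10))
        groups = np.array(["NC"] * 8 + ["aMCI"] * 8 + ["AD"] * 8)
        screen1 = anova_screen(_adjusted_from_matrix(X, groups))
        perm = rng.permutation(24)
        screen2 = anova_screen(_adjusted_from_matrix(X[perm], groups[perm]))
        np.testing.assert_allclose(
            screen1.table["F"].to_numpy(), screen2.table["F"].to_numpy(), rtol=1e-10
        )

    def test_undersized_group_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_screen(_adjusted_from_matrix(X, ["NC", "NC", "aMCI", "aMCI", "AD"]))

    def test_bonferroni_monotonicity(self, rng):
        X = rng.normal(size=(30, 50))
        X[:10] += rng.normal(0, 2, size=(1, 50))  # some group signal
        groups = ["AD"] * 10 + ["aMCI"] * 10 + ["NC"] * 10
        adj = _adjusted_from_matrix(X, groups)
        flags = [
            anova_screen(adj, alpha=a, n_tests=50).table["sig_anova"].sum()
            for a in (0.05, 0.01, 0.001)
        ]
        assert flags[0] >= flags[1] >= flags[2]


class TestPosthoc:
    def test_toy_two_group_t_matches_welch_oracle(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([4.0, 5, 7, 9])
        X = np.concatenate([b, a, a])[:, None]  # AD=b, aMCI=a, NC=a
        groups = ["AD"] * 4 + ["aMCI"] * 4 + ["NC"] * 4
        adj = _adjusted_from_matrix(X, groups)
        screen = posthoc_pairwise(adj, anova_screen(adj), variant="welch")
        assert screen.table["t_ad_nc"].iloc[0] == pytest.approx(oracles.welch_t(b, a))
        t_sp, p_sp = sps.ttest_ind(b, a, equal_var=False)
        assert screen.table["t_ad_nc"].iloc[0] == pytest.approx(t_sp)
        assert screen.table["p_ad_nc"].iloc[0] == pytest.approx(p_sp)

    def test_pooled_variant_matches_scipy(self, rng):
        X = rng.normal(size=(12, 4))
        groups = ["AD"] * 4 + ["aMCI"] * 4 + ["NC"] * 4
        adj = _adjusted_from_matrix(X, groups)
        screen = posthoc_pairwise(adj, anova_screen(adj), variant="pooled")
        t_sp, p_sp = sps.ttest_ind(X[:4], X[8:], equal_var=True)
        np.testing.assert_allclose(screen.table["t_ad_nc"].to_numpy(), t_sp, rtol=1e-10)
        np.testing.assert_allclose(screen.table["p_ad_nc"].to_numpy(), p_sp, rtol=1e-10)

    def test_monotone_effect_ordering(self):
        """With AD shifted far from NC and aMCI intermediate, the AD-NC pair
        should carry the smallest post hoc P in nearly every replicate."""
        rng = np.random.default_rng(1)
        wins = 0
        reps = 100
        for _ in range(reps):
            nc = rng.normal(0, 1, 15)
            amci = rng.normal(1.0, 1, 15)
            ad = rng.normal(2.0, 1, 15)
            X = np.concatenate([nc, amci, ad])[:, None]
            groups = ["NC"] * 15 + ["aMCI"] * 15 + ["AD"] * 15
            adj = _adjusted_from_matrix(X, groups)
            screen = posthoc_pairwise(adj, anova_screen(adj))
            p = screen.table.iloc[0]
            wins += p["p_ad_nc"] <= min(p["p_amci_nc"], p["p_ad_amci"])
        assert wins >= 95

    def test_identical_groups_no_flags(self, rng):
        X = rng.normal(size=(30, 20))
        groups = ["NC"] * 10 + ["aMCI"] * 10 + ["AD"] * 10
        adj = _adjusted_from_matrix(X, groups)
        screen = posthoc_pairwise(adj, anova_screen(adj))
        for key in ("amci_nc", "ad_nc", "ad_amci"):
            assert not screen.table[f"sig_{key}"].any()


class TestSpearman:
    def test_perfect_monotone_rho_one(self):
        rho, p = spearman_rho_p(np.arange(10.0)[:, None] ** 3, np.arange(10.0))
        assert rho[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(0.0)

    def test_matches_rank_oracle_and_scipy(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, 10).astype(float)  # ties exercised
            y = rng.integers(0, 5, 10).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho_p(x[:, None], y)
            assert rho[0] == pytest.approx(oracles.spearman_rho(x, y), abs=1e-12)
            assert rho[0] == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_null_flag_rate_near_nominal(self):
        rng = np.random.default_rng(5)
        reps, n, d = 50, 40, 200
        rates = []
        for _ in range(reps):
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            _, P = spearman_rho_p(X, y)
            rates.append((P < 0.01).mean())
        mean_rate = np.mean(rates)
        se = np.sqrt(0.01 * 0.99 / (reps * d))
        assert abs(mean_rate - 0.01) < 4 * se + 0.002

    def test_screen_subset_and_threshold(self, rng):
        X = rng.normal(size=(30, 8))
        groups = ["NC"] * 10 + ["aMCI"] * 10 + ["AD"] * 10
        adj = _adjusted_from_matrix(X, groups, rng)
        screen = anova_screen(adj)
        scores = adj.covariates["mmse"]
        out = spearman_screen(adj, scores, screen)
        assert "rho_mmse" in out.table.columns
        # default subset excludes NC: correlation computed on 20 patients
        assert out.table["p_mmse"].between(0, 1).all()

    def test_too_few_subjects_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        groups = ["NC", "NC", "aMCI", "aMCI", "AD", "AD"]
        adj = _adjusted_from_matrix(X, groups, rng)
        screen = anova_screen(adj, n_tests=3)
        with pytest.raises(ValueError, match="at least 5"):
            spearman_screen(adj, adj.covariates["mmse"], screen)


class TestMultiRegionSummary:
    def _screen_with_flags(self, flagged_columns):
        cols = registry.subject_columns()
        table = pd.DataFrame(
            {"F": 1.0, "p_anova": 1.0, "sig_anova": [c in flagged_columns for c in cols]},
            index=cols,
        )
        from hipporad.stats import ScreenResult

        return ScreenResult(table=table, alpha=0.01, n_tests=1692)

    def test_one_feature_in_two_subregions(self):
        flagged = {
            registry.make_column("left_caudal", "LLL", "glcm", "entropy"),
            registry.make_column("right_caudal", "LLL", "glcm", "entropy"),
        }
        summary = summarize_multiregion(self._screen_with_flags(flagged))
        assert summary.n_multi == 1

    def test_no_flags_zero(self):
        summary = summarize_multiregion(self._screen_with_flags(set()))
        assert summary.n_multi == 0
        assert summary.per_subregion.sum() == 0

    def test_random_flags_match_set_intersection_oracle(self, rng):
        cols = registry.subject_columns()
        flagged = set(c for c in cols if rng.random() < 0.02)
        summary = summarize_multiregion(self._screen_with_flags(flagged))
        # brute force: base id -> set of subregions with any flagged column
        base_map = {}
        for c in flagged:
            p = registry.parse_column(c)
            base_map.setdefault((p.band, p.family, p.feature), set()).add(p.subregion)
        assert summary.n_multi == sum(1 for v in base_map.values() if len(v) > 1)
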