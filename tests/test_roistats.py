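"""ROI summaries, ANCOVA, demographic tests, PCA reduction, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fdcontrast.fdpipe import BrainMask
from fdcontrast.phantom import LabelPhantom
from fdcontrast.roistats import (
    ancova_group_effect,
    chi2_2x2,
    crossval_classify,
    pca_reduce,
    pooled_t_from_summary,
    roi_means,
    welch_t_from_summary,
)


def _mini_atlas():
    labels = np.zeros((2, 2, 2), dtype=np.int32)
    labels[0, 0, 0] = 1
    labels[0, 0, 1] = 1
    labels[1, 1, 1] = 2
    table = {1: ("roi_a", "GM"), 2: ("roi_b", "WM")}
    return LabelPhantom(labels=labels, label_table=table, voxel_size=(1.0, 1.0, 1.0))


class TestRoiMeans:
    def test_constant_map(self):
        atlas = _mini_atlas()
        out = roi_means(np.full((2, 2, 2), 0.4), atlas)
        assert out["roi_a"] == pytest.approx(0.4)
        assert out["roi_b"] == pytest.approx(0.4)

    def test_two_voxel_mean(self):
        atlas = _mini_atlas()
        vol = np.zeros((2, 2, 2))
        vol[0, 0, 0], vol[0, 0, 1] = 0.2, 0.8
        assert roi_means(vol, atlas)["roi_a"] == pytest.approx(0.5)

    def test_roi_outside_mask_is_missing_not_zero(self):
        atlas = _mini_atlas()
        mask = np.ones((2, 2, 2), bool)
        mask[1, 1, 1] = False
        out = roi_means(np.ones((2, 2, 2)), atlas, BrainMask(mask))
        assert np.isnan(out["roi_b"])

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            roi_means(np.ones((3, 3, 3)), _mini_atlas())


def _normal_equations_oracle(values, is_mci, age):
    """Textbook OLS via explicit normal equations, independent of statsmodels."""
    X = np.column_stack([np.ones(len(values)), is_mci, age])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ values)
    resid = values - X @ beta
    df = len(values) - 3
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[1], t, p


class TestAncova:
    def test_identical_groups_balanced_age_gives_zero(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        group = np.array(["HC"] * 3 + ["MCI"] * 3)
        age = np.array([60, 65, 70, 60, 65, 70], float)
        row = ancova_group_effect(values, group, age)
        assert row["coef_mci_minus_hc"] == pytest.approx(0.0, abs=1e-12)

    def test_six_row_worked_design(self):
        """Hand-solved least squares: adjusted MCI-HC difference = 2/3."""
        values = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 4.0])
        group = np.array(["HC"] * 3 + ["MCI"] * 3)
        age = np.array([60, 65, 70, 60, 65, 70], float)
        row = ancova_group_effect(values, group, age)
        assert row["coef_mci_minus_hc"] == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert row["diff_hc_minus_mci"] == pytest.approx(-2.0 / 3.0, abs=1e-10)
        assert row["df"] == 3
        b, t, p = _normal_equations_oracle(values, (group == "MCI").astype(float), age)
        assert row["t"] == pytest.approx(t, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_agreement_with_normal_equations_on_random_designs(self, rng):
        for _ in range(10):
            n = 12
            values = rng.standard_normal(n)
            group = np.array(["HC"] * 6 + ["MCI"] * 6)
            age = rng.uniform(55, 85, n)
            row = ancova_group_effect(values, group, age)
            b, t, p = _normal_equations_oracle(values, (group == "MCI").astype(float), age)
            assert row["coef_mci_minus_hc"] == pytest.approx(b, rel=1e-6, abs=1e-9)
            assert row["t"] == pytest.approx(t, rel=1e-6)
            assert row["p"] == pytest.approx(p, rel=1e-6)

    def test_reduces_to_pooled_t_without_age_term(self, rng):
        """Dropping the age column recovers the classical two-sample t."""
        for _ in range(5):
            a, b = rng.standard_normal(8), rng.standard_normal(9) + 0.3
            values = np.concatenate([a, b])
            X = np.column_stack(
                [np.ones(17), np.r_[np.zeros(8), np.ones(9)]]
            )
            beta = np.linalg.lstsq(X, values, rcond=None)[0]
            resid = values - X @ beta
            se = np.sqrt(resid @ resid / 15 * np.linalg.inv(X.T @ X)[1, 1])
            t_ols = beta[1] / se
            t_pooled = stats.ttest_ind(b, a, equal_var=True).statistic
            assert t_ols == pytest.approx(t_pooled, rel=1e-10)

    def test_collinear_design_rejected(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        group = np.array(["HC", "HC", "MCI", "MCI"])
        age = np.array([60.0, 60.0, 70.0, 70.0])  # age == group indicator
        with pytest.raises(ValueError):
            ancova_group_effect(values, group, age)

    def test_zero_residual_flagged_not_raised(self):
        values = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        group = np.array(["HC"] * 3 + ["MCI"] * 3)
        age = np.array([60, 65, 70, 61, 66, 71], float)
        row = ancova_group_effect(values, group, age)
        assert row["infinite_stat"]


class TestSummaryStatistics:
    """Group-comparison tests recomputed from printed summary rows."""

    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,p_printed,tol",
        [
            (63.50, 6.55, 16, 70.35, 8.09, 17, 0.0118, 5e-4),   # age
            (16.50, 2.16, 16, 13.94, 4.49, 17, 0.0465, 1e-3),   # odor ID
            (17.38, 2.12, 16, 16.62, 3.26, 17, 0.4325, 2e-2),   # education, years
        ],
    )
    def test_welch_reproduces_printed_p(self, m1, s1, n1, m2, s2, n2, p_printed, tol):
        _, _, p = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
        assert p == pytest.approx(p_printed, abs=tol)

    def test_equal_means_give_t_zero_p_one(self):
        t, _, p = welch_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == 1.0

    def test_pooled_variant_available(self):
        t, df, p = pooled_t_from_summary(63.50, 6.55, 16, 70.35, 8.09, 17)
        assert df == 31
        assert p == pytest.approx(0.0122, abs=5e-4)

    def test_chi2_reproduces_printed_gender_p(self):
        stat, p = chi2_2x2(3, 13, 10, 7)
        assert p == pytest.approx(0.0185, abs=5e-4)

    def test_chi2_identical_rows(self):
        stat, p = chi2_2x2(5, 7, 5, 7)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_four_cell_hand_oracle(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(1, 30, size=4)
            stat, _ = chi2_2x2(a, b, c, d)
            obs = np.array([[a, b], [c, d]], float)
            n = obs.sum()
            exp = np.outer(obs.sum(1), obs.sum(0)) / n
            assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-10)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 3, 4)


class TestPCAReduce:
    def test_single_feature(self, rng):
        red = pca_reduce(rng.standard_normal((10, 1)))
        assert red.n_components == 1
        assert red.explained == pytest.approx(1.0)

    def test_nine_to_one_variance_ratio(self, rng):
        """Uncorrelated features with variance ratio 9:1 -> one component.

        Hand eigendecomposition of diag(9, 1): first component explains 90%.
        Data are constructed with exact sample variances; standardization is
        off so the stated variances are the ones decomposed.
        """
        n = 40
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        b -= a * (a @ b) / (a @ a)          # exactly uncorrelated
        b /= b.std()
        X = np.column_stack([3.0 * a, b])
        red = pca_reduce(X, var_threshold=0.85, standardize=False)
        assert red.n_components == 1
        assert red.explained == pytest.approx(0.9, abs=1e-10)

    def test_threshold_one_keeps_all_components(self, rng):
        X = rng.standard_normal((12, 4))
        red = pca_reduce(X, var_threshold=1.0)
        assert red.n_components == 4

    def test_constant_column_dropped_with_warning(self, rng):
        X = np.column_stack([rng.standard_normal(10), np.full(10, 2.0)])
        with pytest.warns(UserWarning):
            red = pca_reduce(X)
        assert red.kept_columns.tolist() == [0]


def _pair_count_auc(scores, y):
    """Exhaustive midrank pair counting: P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCrossvalClassify:
    def _cohort(self, rng, n=30, separation=0.0, n_feat=6):
        y = np.array(["HC"] * (n // 2) + ["MCI"] * (n - n // 2))
        X = rng.standard_normal((n, n_feat))
        X[y == "MCI", 0] += separation
        df = pd.DataFrame(X, columns=[f"roi{i}" for i in range(n_feat)])
        cov = pd.DataFrame(
            {"age": rng.uniform(55, 85, n), "odor_id": rng.integers(5, 20, n)}
        )
        return df, cov, y

    def test_perfectly_separable_gives_auc_one(self, rng):
        df, cov, y = self._cohort(rng, separation=50.0, n_feat=1)
        for seed in (0, 7, 123):
            assert crossval_classify(df, y, cov, model=1, seed=seed).auc == 1.0

    def test_auc_equals_pair_count_oracle(self, rng):
        df, cov, y = self._cohort(rng, n=18, separation=1.0)
        res = crossval_classify(df, y, cov, model=3, seed=3, k_folds=3)
        assert res.auc == pytest.approx(_pair_count_auc(res.scores, res.y_true), abs=1e-12)

    def test_permutation_null_auc_near_half(self, rng):
        aucs = []
        df, cov, y = self._cohort(rng, n=24, separation=0.0)
        for seed in range(40):
            perm = rng.permutation(len(y))
            aucs.append(crossval_classify(df, y[perm], cov, model=1, seed=seed).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)

    def test_every_subject_in_exactly_one_test_fold(self, rng):
        df, cov, y = self._cohort(rng)
        res = crossval_classify(df, y, cov, model=2, seed=1)
        assert np.all(res.fold_assignment >= 0)
        assert len(np.unique(res.fold_assignment)) == 5
        assert not np.isnan(res.scores).any()

    def test_deterministic_given_seed(self, rng):
        df, cov, y = self._cohort(rng, separation=0.8)
        a = crossval_classify(df, y, cov, model=1, seed=11)
        b = crossval_classify(df, y, cov, model=1, seed=11)
        assert a.auc == b.auc
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.fit_hash == b.fit_hash

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        df, cov, y = self._cohort(rng, separation=1.0)
        res = crossval_classify(df, y, cov, model=1, seed=2)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(res.y_true, np.exp(3 * res.scores)) == pytest.approx(res.auc)

    def test_no_leakage_from_test_labels(self, rng):
        """With folds fixed, corrupting test-fold labels leaves the fitted
        training pipeline (hashed coefficients) unchanged."""
        df, cov, y = self._cohort(rng, separation=0.8)
        from sklearn.model_selection import StratifiedKFold

        ybin = (y == "MCI").astype(int)
        folds = list(StratifiedKFold(5, shuffle=True, random_state=0).split(df, ybin))
        res = crossval_classify(df, y, cov, model=1, folds=folds)
        y_corrupt = y.copy()
        tr0, te0 = folds[0]
        y_corrupt[te0] = np.where(y_corrupt[te0] == "MCI", "HC", "MCI")
        # only fold 0's training pipeline must match (other folds train on te0)
        res_c = crossval_classify(df, y_corrupt, cov, model=1, folds=[folds[0]])
        res_0 = crossval_classify(df, y, cov, model=1, folds=[folds[0]])
        assert res_c.fit_hash == res_0.fit_hash

    def test_fold_missing_a_class_rejected(self, rng):
        df, cov, y = self._cohort(rng, n=12)
        folds = [(np.where(y == "HC")[0], np.where(y == "MCI")[0])]
        with pytest.raises(ValueError):
            crossval_classify(df, y, cov, model=1, folds=folds)
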