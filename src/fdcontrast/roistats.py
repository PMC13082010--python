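"""ROI summaries, age-adjusted group tests, demographics, and classification.

The group comparison is an ANCOVA: ordinary least squares of the ROI value on
an intercept, a group indicator, and age, with a two-sided test of the group
coefficient. Classification is PCA-reduced ROI features feeding a logistic
regression under stratified five-fold cross-validation, scored by the pooled
AUC over concatenated held-out scores.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .fdpipe import BrainMask, FDMap
from .phantom import LabelPhantom

__all__ = [
    "roi_means",
    "roi_table",
    "ancova_group_effect",
    "ancova_table",
    "welch_t_from_summary",
    "pooled_t_from_summary",
    "chi2_2x2",
    "pca_reduce",
    "PCAReduction",
    "crossval_classify",
    "ClassificationResult",
]


def roi_means(
    volume,
    atlas: LabelPhantom,
    mask: BrainMask | None = None,
) -> pd.Series:
    """Mean map value within each atlas ROI, restricted to the mask.

    ``volume`` may be an :class:`FDMap` (its own mask is intersected) or a
    plain 3D array. An ROI with no surviving voxels yields NaN rather than 0.
    """
    if isinstance(volume, FDMap):
        vol = volume.fd
        m = volume.mask.mask.copy()
        if mask is not None:
            m &= mask.mask
    else:
        vol = np.asarray(volume, dtype=float)
        m = mask.mask.copy() if mask is not None else np.ones(vol.shape, dtype=bool)
    if vol.shape != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: map {vol.shape} vs atlas {atlas.labels.shape}"
        )
    out = {}
    for lid, (name, _) in atlas.label_table.items():
        sel = (atlas.labels == lid) & m
        out[name] = float(vol[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, dtype=float)


def roi_table(volumes, atlas: LabelPhantom, mask=None, index=None) -> pd.DataFrame:
    """Stack per-subject ROI means into a subjects x ROIs table."""
    rows = [roi_means(v, atlas, mask) for v in volumes]
    df = pd.DataFrame(rows)
    if index is not None:
        df.index = list(index)
    return df


def ancova_group_effect(values, group, age) -> dict:
    """Age-adjusted group effect for one ROI: value ~ 1 + I(MCI) + age.

    Returns the MCI-vs-HC coefficient (and its negation as HC - MCI), the
    t statistic, two-sided p, and residual df (n - 3). A zero-residual fit is
    flagged rather than raised.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    age = np.asarray(age, dtype=float)
    is_mci = (group == "MCI").astype(float)
    if is_mci.sum() < 2 or (1 - is_mci).sum() < 2:
        raise ValueError("need at least two subjects per group")
    X = sm.add_constant(np.column_stack([is_mci, age]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: group and age are collinear")
    fit = sm.OLS(values, X).fit()
    infinite = fit.ssr <= 1e-14 * max(1.0, float(np.var(values)) * len(values))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = float(fit.tvalues[1])
        p = float(fit.pvalues[1])
    return {
        "coef_mci_minus_hc": float(fit.params[1]),
        "diff_hc_minus_mci": -float(fit.params[1]),
        "t": t,
        "p": p,
        "df": int(fit.df_resid),
        "n_hc": int((1 - is_mci).sum()),
        "n_mci": int(is_mci.sum()),
        "infinite_stat": bool(infinite),
    }


def ancova_table(
    roi_df: pd.DataFrame, group, age, fdr: bool = False
) -> pd.DataFrame:
    """Per-ROI ANCOVA; p-values uncorrected by default (optional BH column)."""
    rows = {}
    for roi in roi_df.columns:
        rows[roi] = ancova_group_effect(roi_df[roi].to_numpy(), group, age)
    out = pd.DataFrame(rows).T
    for c in ("coef_mci_minus_hc", "diff_hc_minus_mci", "t", "p"):
        out[c] = out[c].astype(float)
    if fdr:
        out["p_fdr"] = sm.stats.multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def welch_t_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, float, float]:
    """Welch two-sample t from printed summary statistics.

    Returns (t, Satterthwaite df, two-sided p); the convention is group1 -
    group2 in the numerator.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pooled_t_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, float, float]:
    """Classical equal-variance two-sample t from summary statistics."""
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


def chi2_2x2(a, b, c, d) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction), df = 1."""
    tab = np.array([[a, b], [c, d]], dtype=float)
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("degenerate table: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


@dataclass
class PCAReduction:
    """A fitted standardize+PCA reduction with a held-out projection rule."""

    scaler: StandardScaler
    pca: PCA
    n_components: int
    explained: float
    kept_columns: np.ndarray
    scores: np.ndarray

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        return self.pca.transform(self.scaler.transform(X))[:, : self.n_components]


def pca_reduce(X, var_threshold: float = 0.85, standardize: bool = True) -> PCAReduction:
    """Smallest number of components explaining >= ``var_threshold`` variance.

    Features are z-scored first by default (FD and MVF ROI means live on
    different scales); constant columns are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D feature matrix with >= 2 samples")
    col_sd = X.std(axis=0)
    kept = np.where(col_sd > 0)[0]
    if len(kept) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(kept)} constant feature column(s)")
    if len(kept) == 0:
        raise ValueError("all feature columns are constant")
    Xk = X[:, kept]
    scaler = StandardScaler(with_mean=True, with_std=standardize)
    Xs = scaler.fit_transform(Xk)
    pca = PCA()
    scores = pca.fit_transform(Xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = min(k, len(cum))
    return PCAReduction(
        scaler=scaler,
        pca=pca,
        n_components=k,
        explained=float(cum[k - 1]),
        kept_columns=kept,
        scores=scores[:, :k],
    )


@dataclass
class ClassificationResult:
    """Pooled cross-validated classification outcome."""

    auc: float
    scores: np.ndarray          # held-out probability of the positive class
    y_true: np.ndarray
    fold_assignment: np.ndarray
    n_components: list = field(default_factory=list)
    model: int = 1
    feature_set: str = "FD"
    roi_set: str = "all"
    fit_hash: str = ""


def _fit_logistic(X, y):
    """Unpenalized ML logistic fit, tiny-ridge fallback under separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            clf = LogisticRegression(penalty=None, max_iter=2000)
            clf.fit(X, y)
            return clf
        except Warning:
            pass
        except Exception:
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(C=1e6, max_iter=5000)
        clf.fit(X, y)
    return clf


def crossval_classify(
    roi_df,
    labels,
    covariates: pd.DataFrame | None = None,
    model: int = 1,
    k_folds: int = 5,
    seed: int = 0,
    var_threshold: float = 0.85,
    whole_sample_pca: bool = False,
    feature_set: str = "FD",
    roi_set: str = "all",
    folds=None,
) -> ClassificationResult:
    """Stratified k-fold PCA + logistic classification, pooled AUC.

    Model 1 uses PCA components only; model 2 appends age; model 3 appends
    age and the odor-identification score. The scaler and PCA are fit on the
    training rows of each fold only (``whole_sample_pca=True`` reproduces the
    leakier single-decomposition variant for comparison experiments).
    ``folds`` may supply a precomputed list of (train, test) index arrays,
    bypassing the internal stratified split.
    """
    X = np.asarray(roi_df, dtype=float)
    y = np.asarray([1 if g == "MCI" else 0 for g in np.asarray(labels)])
    if model not in (1, 2, 3):
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    extra_cols: list[str] = [] if model == 1 else (["age"] if model == 2 else ["age", "odor_id"])
    if extra_cols and covariates is None:
        raise ValueError(f"model {model} requires covariates {extra_cols}")
    extras = (
        np.asarray(covariates[extra_cols], dtype=float) if extra_cols else None
    )

    if folds is None:
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    scores = np.full(len(y), np.nan)
    fold_assignment = np.full(len(y), -1)
    n_components = []
    hash_parts = []

    global_red = pca_reduce(X, var_threshold) if whole_sample_pca else None

    for fold, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: training rows contain a single class")
        red = global_red if whole_sample_pca else pca_reduce(X[tr], var_threshold)
        Ztr, Zte = red.transform(X[tr]), red.transform(X[te])
        n_components.append(red.n_components)
        if extras is not None:
            es = StandardScaler().fit(extras[tr])
            Ztr = np.column_stack([Ztr, es.transform(extras[tr])])
            Zte = np.column_stack([Zte, es.transform(extras[te])])
        clf = _fit_logistic(Ztr, y[tr])
        scores[te] = clf.predict_proba(Zte)[:, 1]
        fold_assignment[te] = fold
        hash_parts.append(np.round(clf.coef_, 10).tobytes())

    scored = fold_assignment >= 0
    auc = float(roc_auc_score(y[scored], scores[scored]))
    fit_hash = hashlib.sha256(b"".join(hash_parts)).hexdigest()
    return ClassificationResult(
        auc=auc,
        scores=scores,
        y_true=y,
        fold_assignment=fold_assignment,
        n_components=n_components,
        model=model,
        feature_set=feature_set,
        roi_set=roi_set,
        fit_hash=fit_hash,
    )
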