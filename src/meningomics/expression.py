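"""Expression normalisation, moderated differential expression and grading.

The differential engine is an empirical-Bayes moderated t-test: per-feature
linear models value ~ grade (+ driver stratum) are fit by least squares, the
residual variances are shrunk toward a prior estimated by the method of
moments on the distribution of log residual variances across features
(Smyth-style), and the moderated t has the augmented degrees of freedom
d0 + d.  The same engine backs the miRNA, methylation and ChIP differential
analyses.  On top of it sit the atypical mRNA signature (all features
significant at BH-adjusted p < 0.05), PCA separation of grades on the
signature submatrix, and a top-25-feature random-forest grade classifier
evaluated by its out-of-bag error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

from .errors import DesignError, ValidationError
from .stats import bh_fdr

__all__ = [
    "DEResult",
    "quantile_normalize",
    "batch_adjust",
    "moderated_de",
    "signature_and_pca",
    "rf_grade_classifier",
]

log = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Moderated differential-test output.

    ``table`` has one row per feature: logfc (group effect, first minus
    second level), t (moderated), p, fdr.  ``d0`` and ``s0_sq`` are the
    prior degrees of freedom and prior variance of the shrinkage model.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    residual_df: float

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["fdr"] < alpha]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean quantile distribution.

    Each column's sorted values are replaced by the across-sample mean of
    sorted values; ties within a column receive the mean of their quantiles
    (average ranks).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization requires >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = sps.rankdata(values[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, values.shape[0] + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def batch_adjust(matrix: pd.DataFrame, batch_labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-feature location/scale batch adjustment.

    Every batch's per-feature mean is moved to the grand mean and its SD to
    the pooled SD.  This is the simplified (non-empirical-Bayes) form of
    batch correction; with one batch it is the identity.
    """
    batches = pd.Series({s: batch_labels[s] for s in matrix.columns})
    levels = sorted(batches.unique())
    if len(levels) == 1:
        return matrix.copy()
    counts = batches.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValidationError(f"singleton batch {singletons.index[0]!r}: cannot estimate scale")
    values = matrix.to_numpy(dtype=float)
    grand_mean = values.mean(axis=1, keepdims=True)
    out = np.empty_like(values)
    # pooled within-batch SD per feature
    pooled_var = np.zeros(values.shape[0])
    total_df = 0
    for level in levels:
        cols = np.asarray(batches == level)
        sub = values[:, cols]
        pooled_var += sub.var(axis=1, ddof=1) * (cols.sum() - 1)
        total_df += cols.sum() - 1
    pooled_sd = np.sqrt(pooled_var / total_df)
    for level in levels:
        cols = np.asarray(batches == level)
        sub = values[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        safe_sd = np.where(sd[:, 0] > 0, sd[:, 0], 1.0)[:, None]
        scale = np.where(sd > 0, pooled_sd[:, None], 1.0)
        out[:, cols] = (sub - mu) / safe_sd * scale + grand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vector-safe)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x  # standard starting value
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif / y)) < 1e-10:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model for residual variances.

    Matches the mean and variance of e = log s^2 - digamma(df/2) + log(df/2)
    to the prior (d0, s0^2); returns (d0, s0_sq) with d0 = inf when the
    observed spread is no larger than expected under a shared variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = float(2.0 * _trigamma_inverse(e_var)[0])
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def _design_matrix(
    samples: Sequence[str],
    grades: Mapping[str, str],
    strata: Mapping[str, str] | None,
) -> tuple[np.ndarray, list[str]]:
    grade_levels = sorted({grades[s] for s in samples})
    if len(grade_levels) != 2:
        raise DesignError(f"exactly two grade levels required, got {grade_levels}")
    # contrast: first level (alphabetical, 'atypical' before 'benign') minus the other
    grade_col = np.array([1.0 if grades[s] == grade_levels[0] else 0.0 for s in samples])
    cols = [np.ones(len(samples)), grade_col]
    names = ["intercept", f"grade[{grade_levels[0]}]"]
    if strata is not None:
        stratum_levels = sorted({strata[s] for s in samples})
        for level in stratum_levels[1:]:
            cols.append(np.array([1.0 if strata[s] == level else 0.0 for s in samples]))
            names.append(f"stratum[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design is confounded (grade aliased with stratum or batch)")
    return X, names


def moderated_de(
    matrix: pd.DataFrame,
    grades: Mapping[str, str],
    strata: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> DEResult:
    """Empirical-Bayes moderated two-group test, optionally stratified.

    Fits value ~ grade + stratum per feature; the grade coefficient is the
    log fold change (atypical - benign when those are the level names).
    Residual variances are shrunk toward a moment-matched prior and the
    moderated t uses d0 + d degrees of freedom.
    """
    samples = list(matrix.columns)
    for s in samples:
        if s not in grades:
            raise ValidationError(f"sample {s!r} missing from grade labels")
    counts = pd.Series([grades[s] for s in samples]).value_counts()
    if counts.min() < 2:
        raise DesignError("need >= 2 samples per grade")
    X, names = _design_matrix(samples, grades, strata)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DesignError("no residual degrees of freedom")

    Y = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValidationError("matrix contains non-finite values")
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # features x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid

    d0, s0_sq = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    xtx_inv = np.linalg.inv(X.T @ X)
    grade_idx = 1
    se_factor = np.sqrt(xtx_inv[grade_idx, grade_idx])
    coef = beta[:, grade_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (np.sqrt(s2_tilde) * se_factor)
    if np.isinf(df_total):
        pvals = 2.0 * sps.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * sps.t.sf(np.abs(t), df_total)
    pvals = np.where(np.isfinite(t), pvals, 1.0)

    table = pd.DataFrame(
        {"logfc": coef, "t": t, "p": pvals, "fdr": bh_fdr(pvals)},
        index=matrix.index,
    )
    return DEResult(table=table, d0=float(d0), s0_sq=float(s0_sq), residual_df=float(df_resid))


def signature_and_pca(
    de: DEResult,
    matrix: pd.DataFrame,
    grades: Mapping[str, str],
    alpha: float = 0.05,
    n_components: int = 2,
    random_state: int = 0,
) -> tuple[list[str], pd.DataFrame | None, float | None]:
    """Signature genes (BH-adjusted p < alpha), their PCA embedding and the
    silhouette of grade labels on the first two components."""
    signature = list(de.significant(alpha))
    if not signature:
        log.warning("empty signature at FDR %.3g; PCA skipped", alpha)
        return [], None, None
    sub = matrix.loc[signature].to_numpy(dtype=float)
    sub = (sub - sub.mean(axis=1, keepdims=True))
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sub = sub / np.where(sd > 0, sd, 1.0)
    k = min(n_components, min(sub.shape) - 1, sub.shape[1])
    coords = PCA(n_components=k, random_state=random_state).fit_transform(sub.T)
    labels = [grades[s] for s in matrix.columns]
    sil = None
    if len(set(labels)) > 1 and coords.shape[0] > 2:
        sil = float(silhouette_score(coords[:, : min(2, k)], labels))
    coords_df = pd.DataFrame(coords, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)])
    return signature, coords_df, sil


def rf_grade_classifier(
    matrix: pd.DataFrame,
    grades: Mapping[str, str],
    de: DEResult,
    n_top: int = 25,
    n_trees: int = 5000,
    seed: int = 0,
    test_matrix: pd.DataFrame | None = None,
    test_grades: Mapping[str, str] | None = None,
) -> tuple[RandomForestClassifier, float, float | None]:
    """Random-forest grade classifier on the top differential features.

    Features are the ``n_top`` genes with smallest adjusted p; the model
    reports its out-of-bag error and, when a held-out set is supplied, the
    external accuracy.
    """
    labels = np.array([grades[s] for s in matrix.columns])
    if len(set(labels)) < 2:
        raise DesignError("single-class input; cannot train a classifier")
    ranked = de.table.sort_values(["fdr", "p"], kind="mergesort").index
    features = [f for f in ranked if f in matrix.index][:n_top]
    if len(features) < n_top:
        raise ValidationError(f"requested top {n_top} features but only {len(features)} available")
    X = matrix.loc[features].to_numpy(dtype=float).T
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    model.fit(X, labels)
    oob_error = 1.0 - float(model.oob_score_)
    external = None
    if test_matrix is not None and test_grades is not None:
        Xt = test_matrix.loc[features].to_numpy(dtype=float).T
        yt = np.array([test_grades[s] for s in test_matrix.columns])
        external = float(np.mean(model.predict(Xt) == yt))
    return model, oob_error, external
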