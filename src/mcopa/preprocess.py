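"""Missing-value filtering and K-nearest-feature imputation.

Array matrices routinely carry missing intensities.  Features, then samples,
with more than a given fraction of missing entries are dropped (40% is the
conventional cut-off), and each remaining missing cell is replaced by the mean
of the k nearest features' values in that column.  Nearness is plain Euclidean
distance computed over the samples observed in both features, normalised by the
number of shared samples so that features with different missingness patterns
are comparable; distance ties are broken by feature order so the result is
deterministic.
"""

from __future__ import annotations

import logging

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["preprocess", "filter_missing", "knn_impute"]

logger = logging.getLogger(__name__)


def filter_missing(matrix: ExpressionMatrix, missing_fraction: float = 0.4) -> ExpressionMatrix:
    """Drop features, then samples, whose missing fraction exceeds the threshold.

    The two passes run once each, features first.  Raises if no feature
    survives; sample removal cannot empty the normal or tumour group without
    raising either (the group split must stay valid).
    """
    if not 0.0 < missing_fraction <= 1.0:
        raise ValueError(f"missing_fraction must be in (0, 1], got {missing_fraction}")
    df = matrix.values
    feat_frac = df.isna().mean(axis=1)
    keep_feat = feat_frac <= missing_fraction
    n_dropped_feat = int((~keep_feat).sum())
    df = df.loc[keep_feat]
    if df.empty:
        raise ValueError("empty matrix after filtering: every feature exceeded the missing threshold")

    samp_frac = df.isna().mean(axis=0)
    keep_samp = samp_frac <= missing_fraction
    n_dropped_samp = int((~keep_samp).sum())
    n_normal = int(keep_samp.iloc[: matrix.n_normal].sum())
    df = df.loc[:, keep_samp]
    logger.info(
        "missingness filter: dropped %d/%d features and %d/%d samples (threshold %.0f%%)",
        n_dropped_feat, matrix.n_features, n_dropped_samp, matrix.n_samples,
        100 * missing_fraction,
    )
    if n_normal < 1:
        raise ValueError("all normal samples removed by the missingness filter")
    if df.shape[1] - n_normal < 1:
        raise ValueError("all tumour samples removed by the missingness filter")
    return ExpressionMatrix(df, n_normal)


def _impute_array(x: np.ndarray, k: int) -> np.ndarray:
    """Impute NaNs in a features x samples array by k-nearest-feature means."""
    x = x.copy()
    missing_rows = np.where(np.isnan(x).any(axis=1))[0]
    obs = ~np.isnan(x)
    for i in missing_rows:
        diff = x - x[i]  # NaN wherever either feature is unobserved
        shared = obs & obs[i]
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            # mean squared difference over shared samples; comparable across
            # candidates with different missingness patterns
            d2 = np.nansum(np.where(shared, diff * diff, 0.0), axis=1)
            d2 = np.where(n_shared > 0, d2 / np.maximum(n_shared, 1), np.inf)
        d2[i] = np.inf
        for j in np.where(np.isnan(x[i]))[0]:
            cand = np.where(obs[:, j] & np.isfinite(d2))[0]
            if cand.size == 0:
                raise ValueError(
                    f"cannot impute: no feature observes sample column {j}"
                )
            # stable sort => ties broken by feature order
            nearest = cand[np.argsort(d2[cand], kind="stable")[: min(k, cand.size)]]
            x[i, j] = x[nearest, j].mean()
    return x


def knn_impute(matrix: ExpressionMatrix, k_neighbours: int = 10) -> ExpressionMatrix:
    """Replace every missing entry by the mean of the k nearest features.

    Nearest features are found by Euclidean distance over shared observed
    samples (mean squared difference), excluding the feature itself and any
    feature unobserved in the target column.  If fewer than ``k_neighbours``
    features survive filtering, k is reduced with a warning.
    """
    if k_neighbours < 1:
        raise ValueError(f"k_neighbours must be >= 1, got {k_neighbours}")
    if not matrix.has_missing():
        return matrix
    k = k_neighbours
    if k >= matrix.n_features:
        k = max(1, matrix.n_features - 1)
        logger.warning(
            "k_neighbours=%d >= %d surviving features; reduced to %d",
            k_neighbours, matrix.n_features, k,
        )
    imputed = _impute_array(matrix.values.to_numpy(dtype=float), k)
    out = matrix.values.copy()
    out.iloc[:, :] = imputed
    return ExpressionMatrix(out, matrix.n_normal)


def preprocess(
    matrix: ExpressionMatrix,
    missing_fraction: float = 0.4,
    k_neighbours: int = 10,
) -> ExpressionMatrix:
    """Missingness filter followed by KNN imputation; output has no NaN.

    A matrix without missing values is returned unchanged.
    """
    if not matrix.has_missing():
        return matrix
    filtered = filter_missing(matrix, missing_fraction)
    imputed = knn_impute(filtered, k_neighbours)
    assert not imputed.has_missing()
    # box-plot-style sanity check: per-sample medians of a normalised matrix
    # should be roughly aligned
    med = imputed.values.median(axis=0)
    logger.info(
        "per-sample median range after preprocessing: %.3f .. %.3f",
        float(med.min()), float(med.max()),
    )
    return imputed
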