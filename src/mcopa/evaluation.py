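"""Feature-selection comparators, clustering harness and the adjusted Rand index.

The harness benchmarks four ways of choosing features for clustering tumour
samples into subtypes:

- ``mcopa``: union of the up- and down-retained outlier features;
- ``copa``: features ranked by the nominated upper percentile of their
  transformed tumour values (over-expression ranking only), truncated to the
  mCOPA output size;
- ``de``: differential expression stand-in -- per-feature Welch t-test normal
  vs tumour with Benjamini-Hochberg adjustment (a moderated-t analysis is
  deliberately not reimplemented; the comparator's role is relative
  benchmarking);
- ``variance``: top-k features by sample variance.

Partitions produced by k-means (best of n seeded repeats by within-cluster sum
of squares) or PAM (partitioning around medoids) are scored against annotated
subtypes with the adjusted Rand index, and selector score distributions are
compared with the Kruskal-Wallis rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import OutlierParams
from .matrix import ExpressionMatrix
from .quantiles import resolve_estimator
from .transform import copa_transform

__all__ = [
    "Partition",
    "adjusted_rand_index",
    "variance_select",
    "copa_rank_select",
    "de_select",
    "cluster_samples",
    "kruskal_wallis",
    "evaluate_selection",
    "SelectionResult",
]

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """Cluster assignment per sample."""

    sample_ids: pd.Index
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids)
        self.labels = np.asarray(self.labels)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("labels and sample_ids differ in length")

    def aligned_labels(self, sample_ids: Iterable) -> np.ndarray:
        s = pd.Series(self.labels, index=self.sample_ids)
        missing = [x for x in sample_ids if x not in s.index]
        if missing:
            raise ValueError(f"partition lacks samples: {missing[:5]}")
        return s.loc[list(sample_ids)].to_numpy()


@dataclass
class SelectionResult:
    """Outcome of one feature-selection method."""

    method: str
    selected: list
    scores: pd.Series  # per-feature ranking score (NaN where not ranked)


def _as_labels(part) -> np.ndarray:
    if isinstance(part, Partition):
        return part.labels
    return np.asarray(part)


def adjusted_rand_index(k_part, l_part) -> float:
    """Chance-corrected agreement between two partitions of the same samples.

    Computed from the pair-count contingency table:
    ARI = (Index - E[Index]) / (MaxIndex - E[Index]) with Index the number of
    sample pairs co-clustered in both partitions.  Equals 1 for identical
    partitions and has expectation 0 under random relabelling with fixed
    cluster sizes.  When the denominator is 0 (e.g. both partitions are all
    singletons or a single cluster) the index is defined as 1 if the
    partitions are identical as set partitions, else 0.

    Accepts label sequences aligned to the same sample order, or two
    :class:`Partition` objects over the same sample set (any order).
    """
    if isinstance(k_part, Partition) and isinstance(l_part, Partition):
        if set(k_part.sample_ids) != set(l_part.sample_ids):
            raise ValueError("partitions cover different sample sets")
        order = list(k_part.sample_ids)
        a = k_part.aligned_labels(order)
        b = l_part.aligned_labels(order)
    else:
        a = _as_labels(k_part)
        b = _as_labels(l_part)
        if a.shape != b.shape:
            raise ValueError("partitions have different numbers of samples")
    n = a.size
    if n == 0:
        raise ValueError("empty partitions")

    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    index = comb2(table).sum()
    row = comb2(table.sum(axis=1)).sum()
    col = comb2(table.sum(axis=0)).sum()
    expected = row * col / comb2(n) if n >= 2 else 0.0
    maximum = 0.5 * (row + col)
    denom = maximum - expected
    if denom == 0.0:
        # identical as set partitions <=> the contingency table is a
        # (permuted) diagonal: one nonzero per row and per column
        same = (
            (np.count_nonzero(table, axis=1) == 1).all()
            and (np.count_nonzero(table, axis=0) == 1).all()
        )
        return 1.0 if same else 0.0
    return float((index - expected) / denom)


# ---------------------------------------------------------------------------
# feature selectors
# ---------------------------------------------------------------------------

def variance_select(matrix: ExpressionMatrix, k: int) -> SelectionResult:
    """Top-k features by sample variance (all samples), descending.

    Ties broken by feature order (stable sort).
    """
    if k > matrix.n_features:
        raise ValueError(f"k={k} exceeds feature count {matrix.n_features}")
    var = matrix.values.var(axis=1, ddof=1)
    order = np.argsort(-var.to_numpy(), kind="stable")[:k]
    selected = list(matrix.feature_ids[order])
    return SelectionResult("variance", selected, var)


def copa_rank_select(
    matrix: ExpressionMatrix,
    k: int,
    percentile: float = 90.0,
    params: Optional[OutlierParams] = None,
) -> SelectionResult:
    """Original-style ranking: nominated percentile of transformed tumour values.

    Features are ranked descending by the given percentile of their
    COPA-transformed tumour values (an over-expression ranking) and the top k
    returned.
    """
    if k > matrix.n_features:
        raise ValueError(f"k={k} exceeds feature count {matrix.n_features}")
    params = params or OutlierParams()
    transformed, _ = copa_transform(matrix, params.scale_mode)
    method = resolve_estimator(params.percentile_estimator)
    score = np.quantile(
        transformed.iloc[:, matrix.n_normal :].to_numpy(), percentile / 100.0,
        axis=1, method=method,
    )
    score = pd.Series(score, index=matrix.feature_ids, name=f"copa_p{percentile:g}")
    order = np.argsort(-score.to_numpy(), kind="stable")[:k]
    return SelectionResult("copa", list(matrix.feature_ids[order]), score)


def de_select(matrix: ExpressionMatrix, alpha: float = 0.01) -> SelectionResult:
    """Differential-expression stand-in: Welch t + Benjamini-Hochberg.

    Per feature, a two-sample Welch t-test of normal vs tumour values; BH
    adjustment across features; features with adjusted p < alpha are selected.
    Zero-variance features with identical group means get p = 1.
    """
    if matrix.n_normal < 2 or matrix.n_tumour < 2:
        raise ValueError("need >= 2 samples in each group for the t-test")
    normal = matrix.normal_values.to_numpy(dtype=float)
    tumour = matrix.tumour_values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(tumour, normal, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    # degenerate: both groups constant -> t undefined; identical means are
    # non-discoveries (p=1), different means are certain discoveries (p=0)
    degenerate = np.isnan(pvals)
    if degenerate.any():
        same_mean = np.isclose(tumour.mean(axis=1), normal.mean(axis=1))
        pvals[degenerate & same_mean] = 1.0
        pvals[degenerate & ~same_mean] = 0.0
    adjusted = sps.false_discovery_control(pvals, method="bh")
    adj = pd.Series(adjusted, index=matrix.feature_ids, name="adj_p")
    selected = list(matrix.feature_ids[adjusted < alpha])
    return SelectionResult("de", selected, adj)


def mcopa_select(matrix: ExpressionMatrix, params: Optional[OutlierParams] = None) -> SelectionResult:
    """Union of up- and down-retained outlier features from a full fit."""
    from .model import MCOPA

    results = MCOPA(matrix, params=params).fit()
    n_hits = pd.concat([results.up["n_tumour_outliers"], results.down["n_tumour_outliers"]])
    n_hits = n_hits.groupby(level=0).sum().reindex(matrix.feature_ids)
    return SelectionResult("mcopa", results.selected_features, n_hits)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _pam(x: np.ndarray, n_clusters: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids (BUILD + SWAP) on Euclidean distances.

    Deterministic: the greedy BUILD phase and first-improvement SWAP phase
    involve no randomness; ties resolve to the lowest index.
    """
    n = x.shape[0]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    # BUILD: first medoid minimises total distance; then greedy gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < n_clusters:
        nearest = d[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best = trial, c
                    improved = True
        if not improved:
            break
    return np.argmin(d[:, medoids], axis=1)


def cluster_samples(
    data,
    method: str = "kmeans",
    n_clusters: int = 2,
    n_repeats: int = 20,
    seed: int = 0,
) -> Partition:
    """Cluster samples (rows of ``data``) into ``n_clusters`` groups.

    ``data`` is samples x features (DataFrame or array).  k-means runs
    ``n_repeats`` independently seeded fits and keeps the lowest
    within-cluster sum of squares; PAM is deterministic.  Distances are
    Euclidean on the given feature matrix with no extra scaling.
    """
    df = pd.DataFrame(data)
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from {n} samples")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        ss = np.random.SeedSequence([seed, 0x6B6D])
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_repeats)]
        best = None
        for rs in child_seeds:
            km = KMeans(n_clusters=n_clusters, n_init=1, random_state=rs).fit(x)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        labels = best.labels_
    elif method == "pam":
        labels = _pam(x, n_clusters)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return Partition(df.index, np.asarray(labels))


def kmeans_objective(data, labels) -> float:
    """Within-cluster sum of squares of a labelling (for diagnostics/tests)."""
    x = pd.DataFrame(data).to_numpy(dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels):
        grp = x[labels == c]
        total += ((grp - grp.mean(axis=0)) ** 2).sum()
    return float(total)


def kruskal_wallis(*groups) -> tuple:
    """Kruskal-Wallis H and chi-squared p-value over >= 2 score groups.

    All-identical values across groups give (H=0, p=1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def evaluate_selection(
    matrix: ExpressionMatrix,
    subtype_labels: pd.Series,
    methods: Sequence[str] = ("mcopa", "copa", "de", "variance"),
    clusterers: Sequence[str] = ("kmeans", "pam"),
    n_clusters: Optional[int] = None,
    variance_k: int = 1000,
    de_alpha: float = 0.01,
    params: Optional[OutlierParams] = None,
    n_repeats: int = 20,
    seed: int = 0,
    min_subtype_size: int = 4,
) -> pd.DataFrame:
    """ARI grid: one row per selector, one column per clusterer.

    Subtypes with fewer than ``min_subtype_size`` tumour samples are removed
    before clustering.  Clustering runs on tumour samples only, restricted to
    each selector's features; the number of clusters defaults to the number of
    retained subtypes.  The mCOPA selection is the union of up and down
    outlier features; the original-style ranking is truncated to the same
    size; the variance selector takes ``variance_k`` features.

    The returned DataFrame carries the per-selector Kruskal-Wallis comparison
    in ``df.attrs["kruskal_wallis"]``.
    """
    params = params or OutlierParams()
    labels = pd.Series(subtype_labels)
    missing = [s for s in matrix.tumour_ids if s not in labels.index]
    if missing:
        raise ValueError(f"subtype labels missing for tumour samples: {missing[:5]}")
    labels = labels.loc[list(matrix.tumour_ids)]
    sizes = labels.value_counts()
    kept_subtypes = sizes[sizes >= min_subtype_size].index
    dropped = sizes[sizes < min_subtype_size]
    if len(dropped):
        logger.info("removed %d subtypes with <= %d samples", len(dropped), min_subtype_size - 1)
    keep_samples = labels[labels.isin(kept_subtypes)].index
    if len(kept_subtypes) < 2:
        raise ValueError("fewer than two subtypes remain after the size filter")
    labels = labels.loc[keep_samples]
    k_clusters = n_clusters or len(kept_subtypes)

    selections = {}
    mcopa_result = None
    for m in methods:
        if m == "mcopa":
            mcopa_result = mcopa_select(matrix, params)
            selections[m] = mcopa_result
    mcopa_size = len(mcopa_result.selected) if mcopa_result else variance_k
    for m in methods:
        if m == "copa":
            selections[m] = copa_rank_select(
                matrix, min(max(mcopa_size, 1), matrix.n_features),
                params.upper_percentile, params,
            )
        elif m == "de":
            selections[m] = de_select(matrix, de_alpha)
        elif m == "variance":
            selections[m] = variance_select(matrix, min(variance_k, matrix.n_features))
        elif m != "mcopa":
            raise ValueError(f"unknown selection method {m!r}")

    grid = pd.DataFrame(index=list(methods), columns=list(clusterers), dtype=float)
    truth = labels.to_numpy()
    for m in methods:
        feats = selections[m].selected
        if len(feats) == 0:
            logger.warning("%s selected no features; ARI recorded as NaN", m)
            continue
        sub = matrix.values.loc[feats, keep_samples].T  # samples x features
        for c in clusterers:
            part = cluster_samples(sub, c, k_clusters, n_repeats, seed)
            grid.loc[m, c] = adjusted_rand_index(truth, part.labels)

    score_groups = [grid.loc[m].dropna().to_numpy() for m in methods]
    if all(len(g) for g in score_groups) and len(score_groups) >= 2:
        h, p = kruskal_wallis(*score_groups)
        grid.attrs["kruskal_wallis"] = {"H": h, "p": p}
    grid.index.name = "selector"
    return grid
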