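"""ARI, feature selectors, clustering harness and rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mcopa import (
    OutlierParams,
    Partition,
    adjusted_rand_index,
    cluster_samples,
    copa_rank_select,
    de_select,
    evaluate_selection,
    kruskal_wallis,
    variance_select,
)
from mcopa.evaluation import _pam, kmeans_objective, mcopa_select
from conftest import make_matrix

from _oracles import ari_oracle, bh_adjust


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def test_identical_partitions_score_one():
    rng = np.random.default_rng(1)
    for _ in range(100):
        labels = rng.integers(0, 4, size=rng.integers(2, 30))
        assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)


def test_known_anticorrelated_example_is_minus_half():
    """K={{a,b},{c,d}} vs L={{a,c},{b,d}} -> -0.5, against pair-count oracle."""
    k = [0, 0, 1, 1]
    l = [0, 1, 0, 1]
    assert adjusted_rand_index(k, l) == pytest.approx(-0.5)
    assert ari_oracle(k, l) == pytest.approx(-0.5)


def test_matches_bruteforce_pair_counting_oracle():
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = int(rng.integers(2, 12))
        a = rng.integers(0, 4, n).tolist()
        b = rng.integers(0, 4, n).tolist()
        assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a, b), abs=1e-12)


def test_matches_sklearn_cross_check():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(2, 40))
        a = rng.integers(0, 5, n)
        b = rng.integers(0, 5, n)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12
        )


def test_symmetry_and_label_invariance():
    rng = np.random.default_rng(4)
    for _ in range(50):
        n = int(rng.integers(3, 15))
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        relabel = {0: "x", 1: "y", 2: "z"}
        a2 = np.array([relabel[v] for v in a])
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(a2, b))


def test_permutation_null_mean_is_exactly_zero():
    """Exhaustive relabelling of 6 samples: chance-corrected mean is 0."""
    k = [0, 0, 0, 1, 1, 2]
    base = [0, 0, 0, 1, 1, 2]
    scores = [
        adjusted_rand_index(k, [base[i] for i in perm])
        for perm in itertools.permutations(range(6))
    ]
    assert np.mean(scores) == pytest.approx(0.0, abs=1e-12)


def test_degenerate_denominator_convention():
    # all singletons vs all singletons: identical -> 1
    assert adjusted_rand_index([0, 1, 2], [2, 0, 1]) == 1.0
    # single cluster vs single cluster: identical -> 1
    assert adjusted_rand_index([0, 0, 0], [5, 5, 5]) == 1.0
    # all singletons vs one cluster: not identical -> 0
    assert adjusted_rand_index([0, 1, 2], [0, 0, 0]) == 0.0


def test_partition_objects_align_by_sample_id():
    p1 = Partition(["a", "b", "c", "d"], [0, 0, 1, 1])
    p2 = Partition(["d", "c", "b", "a"], [1, 1, 0, 0])
    assert adjusted_rand_index(p1, p2) == 1.0
    with pytest.raises(ValueError, match="different sample"):
        adjusted_rand_index(p1, Partition(["a", "b"], [0, 1]))


def test_mismatched_lengths_raise():
    with pytest.raises(ValueError):
        adjusted_rand_index([0, 1], [0, 1, 2])


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def test_variance_selects_top_k_in_order():
    m = make_matrix([[5, 5, 5, 5], [0, 4, 0, 4], [1, 2, 1, 2]], n_normal=2)
    res = variance_select(m, 2)
    assert res.selected == ["f2", "f3"]  # constant feature never beats them
    res1 = variance_select(m, 1)
    assert res1.selected == ["f2"]


def test_variance_ranking_agrees_with_exhaustive_sort():
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(0, 1, (100, 12)), n_normal=4)
    res = variance_select(m, 100)
    variances = m.values.var(axis=1, ddof=1)
    expected = [f for f, _ in sorted(variances.items(), key=lambda kv: -kv[1])]
    assert res.selected == expected


def test_copa_rank_prefers_tumour_spike_over_uniform_moderate():
    spike = [0, 0, 0, 0, 0.1, -0.1, 0, 8.0]     # huge in one tumour
    moderate = [0, 0, 0, 0, 1.0, 1.1, 0.9, 1.0]  # mildly raised everywhere
    m = make_matrix([spike, moderate], n_normal=4)
    res = copa_rank_select(m, 1, percentile=90)
    assert res.selected == ["f1"]


def test_copa_rank_full_ordering_and_shift_invariance():
    rng = np.random.default_rng(7)
    vals = rng.normal(0, 1, (20, 10))
    m1 = make_matrix(vals.copy(), n_normal=3)
    vals2 = vals.copy()
    vals2[4] += 100.0  # constant shift leaves the transform unchanged
    m2 = make_matrix(vals2, n_normal=3)
    r1 = copa_rank_select(m1, 20)
    r2 = copa_rank_select(m2, 20)
    assert r1.selected == r2.selected
    assert len(r1.selected) == 20


def test_de_select_null_and_strong_shift():
    rng = np.random.default_rng(8)
    null = rng.normal(0, 1, (50, 20))
    shifted = null.copy()
    shifted[0, 10:] += 10.0  # 10 sigma shift in all tumours
    m = make_matrix(shifted, n_normal=10)
    res = de_select(m, alpha=0.01)
    assert "f1" in res.selected
    m_null = make_matrix(null, n_normal=10)
    res_null = de_select(m_null, alpha=1e-6)
    assert res_null.selected == []


def test_de_select_alpha_extremes():
    rng = np.random.default_rng(9)
    m = make_matrix(rng.normal(0, 1, (30, 12)), n_normal=6)
    assert len(de_select(m, alpha=1.0 + 1e-12).selected) == 30
    assert de_select(m, alpha=1e-15).selected == []


def test_bh_adjustment_matches_hand_computation():
    """(0.001, 0.02, 0.9): adjusted = (0.003, 0.03, 0.9)."""
    from scipy.stats import false_discovery_control

    pvals = [0.001, 0.02, 0.9]
    ours = list(false_discovery_control(pvals, method="bh"))
    expected = bh_adjust(pvals)
    assert ours == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx([0.003, 0.03, 0.9], abs=1e-12)


def test_bh_oracle_agrees_on_random_pvalues():
    from scipy.stats import false_discovery_control

    rng = np.random.default_rng(10)
    for _ in range(50):
        pvals = rng.uniform(0, 1, int(rng.integers(2, 40))).tolist()
        np.testing.assert_allclose(
            false_discovery_control(pvals, method="bh"), bh_adjust(pvals), atol=1e-12
        )


def test_degenerate_zero_variance_features():
    m = make_matrix([[1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 2.0, 2.0]], n_normal=2)
    res = de_select(m, alpha=0.05)
    # identical groups -> p=1 -> never selected; constant-but-shifted -> p=0
    assert "f1" not in res.selected
    assert "f2" in res.selected


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _blobs(seed=0, n_per=8, d=4, sep=8.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, d))
    b = rng.normal(sep, 1, (n_per, d))
    x = np.vstack([a, b])
    truth = np.array([0] * n_per + [1] * n_per)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(2 * n_per)]), truth


@pytest.mark.parametrize("method", ["kmeans", "pam"])
def test_separable_blobs_recovered_perfectly(method):
    x, truth = _blobs()
    part = cluster_samples(x, method, 2, seed=1)
    assert adjusted_rand_index(truth, part.labels) == 1.0


def test_kmeans_deterministic_given_seed():
    x, _ = _blobs(seed=3, sep=2.0)
    p1 = cluster_samples(x, "kmeans", 3, seed=42)
    p2 = cluster_samples(x, "kmeans", 3, seed=42)
    np.testing.assert_array_equal(p1.labels, p2.labels)


def test_kmeans_best_of_repeats_objective():
    """The returned partition's WCSS is <= every single-repeat WCSS."""
    from sklearn.cluster import KMeans

    x, _ = _blobs(seed=5, sep=1.5)
    arr = x.to_numpy()
    best = cluster_samples(x, "kmeans", 3, n_repeats=10, seed=7)
    best_obj = kmeans_objective(arr, best.labels)
    ss = np.random.SeedSequence([7, 0x6B6D])
    for child in ss.spawn(10):
        rs = int(child.generate_state(1)[0] % (2**31))
        km = KMeans(n_clusters=3, n_init=1, random_state=rs).fit(arr)
        assert best_obj <= kmeans_objective(arr, km.labels_) + 1e-9


def test_pam_matches_reference_r_cluster_pam():
    """Frozen cross-check against R's cluster::pam on two fixtures."""
    rng = np.random.default_rng(42)
    centers = np.array([[0, 0], [6, 0], [0, 6]])
    x = np.vstack([c + rng.normal(0, 1, (5, 2)) for c in centers])
    got = _pam(x, 3).tolist()
    assert got == [0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2]

    rng = np.random.default_rng(7)
    x2 = rng.normal(0, 1, (14, 3))
    x2[7:, 0] += 1.5
    got2 = _pam(x2, 2).tolist()
    # cluster::pam clustering vector 1 1 2 2 1 1 1 2 1 2 1 2 2 2 (0-based here)
    assert got2 == [0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 0, 1, 1, 1]


def test_cluster_errors():
    x, _ = _blobs(n_per=2)
    with pytest.raises(ValueError, match="cannot form"):
        cluster_samples(x, "kmeans", 10)
    with pytest.raises(ValueError, match="unknown clustering"):
        cluster_samples(x, "magic", 2)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups_h_zero():
    h, p = kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0])
    assert h == 0.0 and p == 1.0


def test_kruskal_matches_hand_ranked_computation():
    """Groups (1,2,3) vs (4,5,6): ranks 1..6, H = 12/(n(n+1)) * sum(ni*(Ri-R)^2)."""
    h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
    # mean ranks 2 and 5; grand mean 3.5; H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2)
    expected_h = 12.0 / 42.0 * (3 * 1.5**2 + 3 * 1.5**2)
    assert h == pytest.approx(expected_h, abs=1e-12)
    assert 0 < p < 0.05


def test_kruskal_exchangeable_within_groups():
    h1, _ = kruskal_wallis([3, 1, 2], [6, 4, 5], [9, 7, 8])
    h2, _ = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
    assert h1 == pytest.approx(h2)


def test_kruskal_bad_input():
    with pytest.raises(ValueError):
        kruskal_wallis([1.0])
    with pytest.raises(ValueError):
        kruskal_wallis([1.0], [])


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def _structured_dataset(seed=0):
    from mcopa import generate
    from mcopa.synthetic import SimulationConfig, subtype_labels

    cfg = SimulationConfig(n_features=600, n_outlier_features=60, n_de_features=30,
                           n_noise_features=30, seed=seed)
    m, _ = generate(cfg)
    return m, subtype_labels(cfg)


def test_grid_dimensions_and_score_range():
    m, labels = _structured_dataset(1)
    grid = evaluate_selection(
        m, labels, methods=("mcopa", "variance"), clusterers=("kmeans", "pam"),
        variance_k=200, seed=3,
    )
    assert grid.shape == (2, 2)
    assert ((grid <= 1.0 + 1e-9) | grid.isna()).all().all()
    assert "kruskal_wallis" in grid.attrs


def test_perfectly_structured_data_scores_one():
    # two subtypes with massive disjoint recurrent signal
    rng = np.random.default_rng(13)
    vals = rng.normal(0, 0.2, (60, 16))
    vals[:10, 4:10] += 6.0   # subtype 1 block (tumours T1..T6)
    vals[10:20, 10:16] += 6.0  # subtype 2 block
    m = make_matrix(vals, n_normal=4)
    labels = pd.Series(
        ["A"] * 6 + ["B"] * 6, index=[f"T{i+1}" for i in range(12)]
    )
    grid = evaluate_selection(
        m, labels, methods=("variance",), clusterers=("kmeans", "pam"),
        variance_k=20, seed=1,
    )
    assert (grid.loc["variance"] == 1.0).all()


def test_small_subtypes_removed_and_errors():
    m, labels = _structured_dataset(2)
    labels = labels.copy()
    labels.iloc[:2] = "tiny"  # a 2-sample subtype is dropped
    grid = evaluate_selection(
        m, labels, methods=("variance",), clusterers=("kmeans",), variance_k=50,
    )
    assert grid.shape == (1, 1)
    with pytest.raises(ValueError, match="missing"):
        evaluate_selection(m, labels.iloc[:5], methods=("variance",))


def test_mcopa_selection_is_union_of_directions():
    m, _ = _structured_dataset(3)
    from mcopa import MCOPA

    res = MCOPA(m).fit()
    sel = mcopa_select(m)
    assert set(sel.selected) == set(res.up.index) | set(res.down.index)
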