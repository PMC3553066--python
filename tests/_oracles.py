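"""Independent brute-force oracles used by the test suite.

Everything here is coded from textbook definitions, deliberately avoiding the
package's own code paths (and numpy's quantile machinery) so that agreement is
meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations


def sorted_copy(values):
    return sorted(float(v) for v in values)


def median_oracle(values):
    x = sorted_copy(values)
    n = len(x)
    mid = n // 2
    if n % 2:
        return x[mid]
    return 0.5 * (x[mid - 1] + x[mid])


def mad_oracle(values):
    m = median_oracle(values)
    return median_oracle([abs(v - m) for v in values])


def meanad_oracle(values):
    m = median_oracle(values)
    return sum(abs(v - m) for v in values) / len(values)


# Hyndman-Fan plotting-position constants for the continuous types 4-9:
# h = a + p * (n + b); Q = x_floor(h) + (h - floor(h)) * (x_floor(h)+1 - x_floor(h))
_HF_CONTINUOUS = {
    4: (0.0, 0.0),          # h = n*p
    5: (0.5, 0.0),          # h = n*p + 1/2
    6: (0.0, 1.0),          # h = (n+1)*p
    7: (1.0, -1.0),         # h = (n-1)*p + 1
    8: (1.0 / 3.0, 1.0 / 3.0),   # h = (n+1/3)*p + 1/3
    9: (3.0 / 8.0, 1.0 / 4.0),   # h = (n+1/4)*p + 3/8
}


def hf_quantile(values, p, qtype):
    """Sample quantile of ``values`` at probability ``p`` (0..1), HF type 1-9."""
    x = sorted_copy(values)
    n = len(x)
    if n == 1:
        return x[0]
    if qtype in _HF_CONTINUOUS:
        a, b = _HF_CONTINUOUS[qtype]
        h = a + p * (n + b)
        h = min(max(h, 1.0), float(n))
        j = int(math.floor(h))
        g = h - j
        if j >= n:
            return x[n - 1]
        return x[j - 1] + g * (x[j] - x[j - 1])
    np_ = n * p
    if qtype == 1:
        j = max(1, math.ceil(np_))
        return x[j - 1]
    if qtype == 2:
        if np_ >= n:
            return x[n - 1]
        if abs(np_ - round(np_)) < 1e-12 and np_ >= 1:
            j = int(round(np_))
            return 0.5 * (x[j - 1] + x[j])
        return x[max(1, math.ceil(np_)) - 1]
    if qtype == 3:
        # nearest order statistic to h = n*p - 1/2, halves rounded to even j
        h = np_ - 0.5
        j = math.floor(h)
        g = h - j
        if g > 1e-12:
            j = j + 1
        elif j % 2 == 1:
            j = j + 1
        j = min(max(j, 1), n)
        return x[j - 1]
    raise ValueError(f"unknown quantile type {qtype}")


def ari_oracle(labels_a, labels_b):
    """Adjusted Rand index by explicit enumeration of all sample pairs."""
    n = len(labels_a)
    assert n == len(labels_b)
    both = neither = only_a = only_b = 0
    for i, j in combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            both += 1
        elif same_a:
            only_a += 1
        elif same_b:
            only_b += 1
        else:
            neither += 1
    total = both + neither + only_a + only_b
    sum_a = both + only_a   # pairs together in A
    sum_b = both + only_b   # pairs together in B
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        return 1.0 if (only_a == 0 and only_b == 0) else 0.0
    return (both - expected) / (maximum - expected)


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = pvalues[i] * m / rank_from_end
        running_min = min(running_min, val)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def knn_impute_oracle(rows, target_row, target_col, k):
    """Exhaustive nearest-feature search for one missing cell.

    ``rows``: list of lists with None for missing.  Distance between features
    is the mean squared difference over columns observed in both.
    """
    dists = []
    for idx, row in enumerate(rows):
        if idx == target_row or row[target_col] is None:
            continue
        shared = [
            (a, b)
            for a, b in zip(rows[target_row], row)
            if a is not None and b is not None
        ]
        if not shared:
            continue
        d2 = sum((a - b) ** 2 for a, b in shared) / len(shared)
        dists.append((d2, idx))
    dists.sort()
    nearest = [idx for _, idx in dists[:k]]
    return sum(rows[i][target_col] for i in nearest) / len(nearest)
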