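"""Percentile estimation with selectable interpolation rules.

Quantile estimates from small sample vectors (a feature's values within one
group are often 10-30 numbers) are sensitive to the interpolation rule, so the
rule is an explicit, logged parameter rather than an implicit library default.
The nine classical sample-quantile definitions of Hyndman & Fan are supported,
either by their conventional type number (1-9) or by name.  The default is the
median-unbiased rule (type 8), the usual recommendation when the underlying
distribution is unknown.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

__all__ = ["percentile", "ESTIMATORS", "DEFAULT_ESTIMATOR", "resolve_estimator"]

#: Hyndman-Fan type number -> numpy.quantile ``method`` name.
ESTIMATORS: dict[int, str] = {
    1: "inverted_cdf",
    2: "averaged_inverted_cdf",
    3: "closest_observation",
    4: "interpolated_inverted_cdf",
    5: "hazen",
    6: "weibull",
    7: "linear",
    8: "median_unbiased",
    9: "normal_unbiased",
}

_NAME_TO_TYPE = {name: t for t, name in ESTIMATORS.items()}

DEFAULT_ESTIMATOR = "median_unbiased"


def resolve_estimator(estimator: Union[int, str, None]) -> str:
    """Normalise an estimator spec (type number or name) to a numpy method name."""
    if estimator is None:
        return DEFAULT_ESTIMATOR
    if isinstance(estimator, (int, np.integer)):
        try:
            return ESTIMATORS[int(estimator)]
        except KeyError:
            raise ValueError(
                f"unknown quantile estimator type {estimator}; expected 1-9"
            ) from None
    if estimator in _NAME_TO_TYPE:
        return str(estimator)
    raise ValueError(
        f"unknown quantile estimator {estimator!r}; "
        f"expected a type number 1-9 or one of {sorted(_NAME_TO_TYPE)}"
    )


def percentile(
    values: Sequence[float],
    p: float,
    estimator: Union[int, str, None] = None,
) -> float:
    """p-th percentile of ``values`` under the selected interpolation rule.

    Parameters
    ----------
    values
        Non-empty sequence of real numbers (NaN not allowed).
    p
        Percentile in [0, 100].
    estimator
        Hyndman-Fan type number (1-9) or numpy method name; default type 8.

    Returns
    -------
    float
        The percentile; always within [min(values), max(values)].
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample: cannot compute a percentile")
    if np.isnan(arr).any():
        raise ValueError("values contain NaN; impute or drop before percentile()")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile p must be in [0, 100], got {p}")
    method = resolve_estimator(estimator)
    return float(np.quantile(arr, p / 100.0, method=method))
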