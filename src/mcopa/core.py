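"""Feature-specific outlier fences and the three-criterion filter.

A (feature, sample) pair is an over-expressed outlier when the feature's
transformed value in that sample exceeds Q75 + 1.5*IQR of the feature's
transformed *tumour* values (under-expressed: below Q25 - 1.5*IQR).  Fences
come from tumour samples only but are applied to every sample, normals
included, so the subsequent filter can see outliers arising in normal tissue.

A feature is retained, per direction, when

1. it is an outlier in at least one tumour sample;
2. it is not an outlier of the same direction in any normal sample
   (opposite-direction normal outliers are permitted); and
3. the nominated upper (down: lower) percentiles of the tumour and normal
   groups differ by more than the fold-change threshold (2 by default,
   corresponding to a log2 fold change of 2 on log-scale input).

Criterion 3 can be evaluated on three scales (``fc_scale``): the transformed
COPA percentiles (default; the workflow computes its percentiles on COPA
scores), the pre-transform log2 input values, or a linear ratio of raw values
for inputs that are not log-scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .quantiles import DEFAULT_ESTIMATOR, percentile, resolve_estimator
from .transform import SCALE_MODES, TransformStats, copa_transform

__all__ = [
    "OutlierParams",
    "FeatureFences",
    "OutlierCallSet",
    "compute_fences",
    "call_outliers",
    "filter_outliers",
    "run_mcopa",
]

logger = logging.getLogger(__name__)

FC_SCALES = ("copa", "log2input", "ratio")


@dataclass(frozen=True)
class OutlierParams:
    """Tuning parameters of the outlier pipeline.

    Attributes
    ----------
    upper_percentile, lower_percentile
        Nominated percentiles used by the fold-change filter (criterion 3);
        defaults 90 and 10.  Constrained to lower < 25 < 75 < upper.
    fence_multiplier
        Tukey fence width in IQR units; 1.5 by convention.
    fc_threshold
        Criterion-3 threshold; 2 by convention (a log2 fold change of 2,
        i.e. four-fold, on log2-scale input).
    percentile_estimator
        Quantile interpolation rule (Hyndman-Fan type 1-9 or name) used for
        every percentile in the pipeline; default type 8 (median-unbiased).
    scale_mode
        Robust scale of the transform: "meanad" (default) or "mad".
    fc_scale
        Scale on which criterion 3 compares percentiles: "copa" (default,
        difference of transformed percentiles), "log2input" (difference of
        raw log2-scale percentiles), or "ratio" (log2 of the absolute ratio
        of raw linear percentiles).
    """

    upper_percentile: float = 90.0
    lower_percentile: float = 10.0
    fence_multiplier: float = 1.5
    fc_threshold: float = 2.0
    percentile_estimator: Union[int, str] = DEFAULT_ESTIMATOR
    scale_mode: str = "meanad"
    fc_scale: str = "copa"

    def __post_init__(self) -> None:
        if not (self.lower_percentile < 25.0 < 75.0 < self.upper_percentile <= 100.0):
            raise ValueError(
                "percentiles must satisfy lower < 25 < 75 < upper <= 100, got "
                f"lower={self.lower_percentile}, upper={self.upper_percentile}"
            )
        if self.lower_percentile < 0.0:
            raise ValueError("lower_percentile must be >= 0")
        if self.fence_multiplier <= 0.0:
            raise ValueError("fence_multiplier must be > 0")
        if self.fc_threshold <= 0.0:
            raise ValueError("fc_threshold must be > 0")
        resolve_estimator(self.percentile_estimator)  # validates
        if self.scale_mode not in SCALE_MODES:
            raise ValueError(f"scale_mode must be one of {SCALE_MODES}")
        if self.fc_scale not in FC_SCALES:
            raise ValueError(f"fc_scale must be one of {FC_SCALES}")


@dataclass
class FeatureFences:
    """Per-feature fences and group percentiles.

    ``table`` columns:

    - ``q25_t``, ``q75_t``, ``iqr_t`` -- tumour quartiles of transformed values;
    - ``upper_fence``, ``lower_fence`` -- Tukey fences on the transformed scale;
    - ``pu_t``, ``pl_t``, ``pu_n``, ``pl_n`` -- nominated upper/lower percentiles
      of tumour and normal groups on the transformed (COPA) scale;
    - ``pu_t_raw``, ``pl_t_raw``, ``pu_n_raw``, ``pl_n_raw`` -- the same on the
      pre-transform expression scale;
    - ``degenerate`` -- zero robust scale or zero tumour IQR; excluded from
      calling.
    """

    table: pd.DataFrame
    params: OutlierParams

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class OutlierCallSet:
    """Raw (unfiltered) outlier calls: +1 up, -1 down, 0 none, per cell."""

    codes: pd.DataFrame  # features x samples, int8
    n_normal: int

    @property
    def normal_codes(self) -> pd.DataFrame:
        return self.codes.iloc[:, : self.n_normal]

    @property
    def tumour_codes(self) -> pd.DataFrame:
        return self.codes.iloc[:, self.n_normal :]


def _group_quantiles(
    values: np.ndarray, qs: list[float], method: str
) -> np.ndarray:
    """Row-wise quantiles; returns array of shape (len(qs), n_features)."""
    return np.quantile(values, qs, axis=1, method=method)


def compute_fences(
    transformed: pd.DataFrame,
    matrix: ExpressionMatrix,
    stats: TransformStats,
    params: Optional[OutlierParams] = None,
) -> FeatureFences:
    """Tumour-group Tukey fences plus nominated group percentiles per feature.

    Fences use the transformed tumour values only.  The nominated upper/lower
    percentiles are recorded for both groups on both the transformed and the
    raw expression scale, for use by the fold-change filter.
    """
    params = params or OutlierParams()
    n_normal = matrix.n_normal
    if matrix.n_tumour < 2:
        raise ValueError(f"need >= 2 tumour samples to compute fences, got {matrix.n_tumour}")
    method = resolve_estimator(params.percentile_estimator)
    pu, pl = params.upper_percentile / 100.0, params.lower_percentile / 100.0

    t_z = transformed.iloc[:, n_normal:].to_numpy(dtype=float)
    n_z = transformed.iloc[:, :n_normal].to_numpy(dtype=float)
    t_raw = matrix.tumour_values.to_numpy(dtype=float)
    n_raw = matrix.normal_values.to_numpy(dtype=float)

    q25, q75, pu_t, pl_t = _group_quantiles(t_z, [0.25, 0.75, pu, pl], method)
    pu_n, pl_n = _group_quantiles(n_z, [pu, pl], method)
    pu_t_raw, pl_t_raw = _group_quantiles(t_raw, [pu, pl], method)
    pu_n_raw, pl_n_raw = _group_quantiles(n_raw, [pu, pl], method)

    iqr = q75 - q25
    m = params.fence_multiplier
    table = pd.DataFrame(
        {
            "q25_t": q25,
            "q75_t": q75,
            "iqr_t": iqr,
            "upper_fence": q75 + m * iqr,
            "lower_fence": q25 - m * iqr,
            "pu_t": pu_t,
            "pl_t": pl_t,
            "pu_n": pu_n,
            "pl_n": pl_n,
            "pu_t_raw": pu_t_raw,
            "pl_t_raw": pl_t_raw,
            "pu_n_raw": pu_n_raw,
            "pl_n_raw": pl_n_raw,
            "degenerate": stats.degenerate.to_numpy() | (iqr == 0.0),
        },
        index=transformed.index,
    )
    n_deg = int(table["degenerate"].sum())
    if n_deg:
        logger.info("%d features are degenerate (zero scale or zero tumour IQR); excluded from calling", n_deg)
    return FeatureFences(table, params)


def call_outliers(
    transformed: pd.DataFrame,
    fences: FeatureFences,
    n_normal: int,
) -> OutlierCallSet:
    """Strict fence comparison for every (feature, sample), normals included.

    Values exactly on a fence are non-outliers.  Degenerate features produce
    no calls.
    """
    z = transformed.to_numpy(dtype=float)
    upper = fences["upper_fence"].to_numpy()[:, None]
    lower = fences["lower_fence"].to_numpy()[:, None]
    codes = np.zeros(z.shape, dtype=np.int8)
    codes[z > upper] = 1
    codes[z < lower] = -1
    codes[fences["degenerate"].to_numpy(), :] = 0
    return OutlierCallSet(
        pd.DataFrame(codes, index=transformed.index, columns=transformed.columns),
        n_normal,
    )


def _fold_change_pass(fences: FeatureFences, direction: str) -> pd.Series:
    """Criterion 3: nominated-percentile separation above the threshold."""
    params = fences.params
    if direction == "up":
        copa_pair = ("pu_t", "pu_n")
        raw_pair = ("pu_t_raw", "pu_n_raw")
    else:
        copa_pair = ("pl_t", "pl_n")
        raw_pair = ("pl_t_raw", "pl_n_raw")
    if params.fc_scale == "copa":
        diff = fences[copa_pair[0]] - fences[copa_pair[1]]
        return diff.abs() > params.fc_threshold
    if params.fc_scale == "log2input":
        diff = fences[raw_pair[0]] - fences[raw_pair[1]]
        return diff.abs() > params.fc_threshold
    # linear-ratio mode for non-log input; undefined ratios fail the criterion
    num = fences[raw_pair[0]].to_numpy()
    den = fences[raw_pair[1]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(np.abs(num / den))
    ok = np.isfinite(lfc) & (lfc > params.fc_threshold)
    return pd.Series(ok, index=fences.feature_ids)


def filter_outliers(
    calls: OutlierCallSet,
    fences: FeatureFences,
    direction: str,
) -> pd.DataFrame:
    """Apply the three retention criteria for one direction.

    Returns a table indexed by retained feature id with columns:
    ``outlier_samples`` (list of tumour sample ids), ``n_tumour_outliers``,
    and the criterion-3 percentile pair on the scale used (``p_t``, ``p_n``).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    code = 1 if direction == "up" else -1

    t_hit = calls.tumour_codes.eq(code)
    n_hit = calls.normal_codes.eq(code)
    c1 = t_hit.any(axis=1)
    c2 = ~n_hit.any(axis=1)
    c3 = _fold_change_pass(fences, direction)
    keep = c1 & c2 & c3 & ~fences["degenerate"]
    logger.info(
        "%s filter: %d features in; criterion1 pass %d; +criterion2 %d; +criterion3 %d retained",
        direction, len(keep), int(c1.sum()), int((c1 & c2).sum()), int(keep.sum()),
    )

    if fences.params.fc_scale == "copa":
        p_t, p_n = ("pu_t", "pu_n") if direction == "up" else ("pl_t", "pl_n")
    else:
        p_t, p_n = ("pu_t_raw", "pu_n_raw") if direction == "up" else ("pl_t_raw", "pl_n_raw")

    kept = keep[keep].index
    hits = t_hit.loc[kept]
    tumour_ids = calls.tumour_codes.columns
    out = pd.DataFrame(
        {
            "outlier_samples": [
                [s for s in tumour_ids if hits.at[f, s]] for f in kept
            ],
            "n_tumour_outliers": hits.sum(axis=1).astype(int),
            "p_t": fences[p_t].loc[kept],
            "p_n": fences[p_n].loc[kept],
        },
        index=kept,
    )
    out.index.name = "feature_id"
    return out


def run_mcopa(
    matrix: ExpressionMatrix,
    params: Optional[OutlierParams] = None,
):
    """Full pipeline on a preprocessed matrix; see :class:`mcopa.MCOPA`.

    Returns an :class:`mcopa.model.MCOPAResults` with the up/down feature
    tables and the outlier profile.
    """
    from .model import MCOPA

    return MCOPA(matrix, params=params).fit()
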