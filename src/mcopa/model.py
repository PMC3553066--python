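"""Model/results interface tying the pipeline together.

``MCOPA`` holds the data and parameters; ``fit()`` runs transform -> fences ->
calls -> filter for both directions and returns an ``MCOPAResults`` carrying
the retained feature tables, the outlier profile and per-stage diagnostics.
The individual stages remain available as functions in :mod:`mcopa.core` for
piecemeal use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

from .core import (
    FeatureFences,
    OutlierCallSet,
    OutlierParams,
    call_outliers,
    compute_fences,
    filter_outliers,
)
from .matrix import ExpressionMatrix
from .preprocess import preprocess
from .profiles import (
    OutlierProfile,
    build_profiles,
    sample_outlier_lists,
    sharing_histogram,
    subtype_outliers,
)
from .transform import TransformStats, copa_transform

__all__ = ["MCOPA", "MCOPAResults"]

logger = logging.getLogger(__name__)


class MCOPA:
    """Outlier-profile model for a normal/tumour expression matrix.

    Parameters
    ----------
    data
        :class:`ExpressionMatrix`, or a features x samples DataFrame together
        with ``n_normal``.
    n_normal
        Count of leading normal/control columns (required when ``data`` is a
        DataFrame).
    params
        :class:`OutlierParams`; defaults are the conventional 90/10
        percentiles, 1.5 IQR fences and a fold-change threshold of 2.
    preprocess_missing
        When True, matrices with missing entries are filtered (40% rule) and
        KNN-imputed (k=10) before fitting; otherwise missing values raise.
    """

    def __init__(
        self,
        data: Union[ExpressionMatrix, pd.DataFrame],
        n_normal: Optional[int] = None,
        params: Optional[OutlierParams] = None,
        preprocess_missing: bool = False,
        missing_fraction: float = 0.4,
        k_neighbours: int = 10,
    ) -> None:
        if isinstance(data, ExpressionMatrix):
            matrix = data
        else:
            if n_normal is None:
                raise ValueError("n_normal is required when data is a DataFrame")
            matrix = ExpressionMatrix(pd.DataFrame(data), n_normal)
        if matrix.has_missing():
            if not preprocess_missing:
                raise ValueError(
                    "matrix contains missing values; pass preprocess_missing=True "
                    "or run mcopa.preprocess() first"
                )
            matrix = preprocess(matrix, missing_fraction, k_neighbours)
        self.matrix = matrix
        self.params = params or OutlierParams()

    @classmethod
    def from_tsv(
        cls,
        path,
        n_normal: int,
        params: Optional[OutlierParams] = None,
        **kwargs,
    ) -> "MCOPA":
        return cls(ExpressionMatrix.from_tsv(path, n_normal), params=params, **kwargs)

    def fit(self) -> "MCOPAResults":
        """Run the full pipeline; deterministic for fixed input and params."""
        transformed, stats = copa_transform(self.matrix, self.params.scale_mode)
        fences = compute_fences(transformed, self.matrix, stats, self.params)
        calls = call_outliers(transformed, fences, self.matrix.n_normal)
        up = filter_outliers(calls, fences, "up")
        down = filter_outliers(calls, fences, "down")
        profile = _calls_to_profile(up, down, calls)
        return MCOPAResults(
            model=self,
            transformed=transformed,
            transform_stats=stats,
            fences=fences,
            calls=calls,
            up=up,
            down=down,
            profile=profile,
        )


def _calls_to_profile(
    up: pd.DataFrame, down: pd.DataFrame, calls: OutlierCallSet
) -> OutlierProfile:
    """Profile over all samples for features retained in either direction.

    Codes come from the retained tumour calls; for a feature retained in one
    direction only, calls of the other direction are not shown (they did not
    survive filtering).  Normal-sample codes are zero by construction of the
    filter for the retained direction.
    """
    return build_profiles(up, down, calls.codes.columns)


@dataclass
class MCOPAResults:
    """Fitted outlier tables, profile and diagnostics.

    Attributes
    ----------
    up, down
        Retained feature tables per direction (feature id -> outlier tumour
        samples, counts, criterion-3 percentile pair).
    profile
        :class:`OutlierProfile` over all samples.
    transformed, transform_stats, fences, calls
        Intermediate stages, kept for inspection.
    """

    model: MCOPA
    transformed: pd.DataFrame
    transform_stats: TransformStats
    fences: FeatureFences
    calls: OutlierCallSet
    up: pd.DataFrame
    down: pd.DataFrame
    profile: OutlierProfile

    # -- convenience ------------------------------------------------------
    @property
    def params(self) -> OutlierParams:
        return self.model.params

    @property
    def selected_features(self) -> list:
        """Union of up- and down-retained features (order: up first)."""
        seen = list(self.up.index) + [
            f for f in self.down.index if f not in set(self.up.index)
        ]
        return seen

    def subtype_outliers(self, subtype_samples: Iterable[str], direction: str = "both",
                         exclusive: bool = True) -> list:
        return subtype_outliers(self.profile, subtype_samples, direction, exclusive)

    def sample_outlier_lists(self) -> pd.DataFrame:
        return sample_outlier_lists(self.profile)

    def sharing_histogram(self, subtype_samples: Iterable[str], direction: str = "both"):
        return sharing_histogram(self.profile, subtype_samples, direction)

    def plot_sharing(self, subtype_samples=None, ax=None):
        return self.profile.plot_sharing(subtype_samples, ax=ax)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Plain-text run summary: data shape, parameters, per-stage counts."""
        m = self.model.matrix
        p = self.params
        deg = int(self.fences["degenerate"].sum())
        n_up_calls = int((self.calls.codes.to_numpy() == 1).sum())
        n_down_calls = int((self.calls.codes.to_numpy() == -1).sum())
        lines = [
            "mCOPA outlier analysis",
            "=" * 54,
            f"features:                {m.n_features}",
            f"samples:                 {m.n_samples} ({m.n_normal} normal, {m.n_tumour} tumour)",
            f"percentiles (up/low):    {p.upper_percentile:g} / {p.lower_percentile:g}",
            f"estimator:               {p.percentile_estimator}",
            f"scale mode:              {p.scale_mode}",
            f"fence multiplier:        {p.fence_multiplier:g} x IQR",
            f"fold-change threshold:   {p.fc_threshold:g} (scale: {p.fc_scale})",
            "-" * 54,
            f"degenerate features:     {deg}",
            f"raw up/down calls:       {n_up_calls} / {n_down_calls}",
            f"retained up features:    {len(self.up)}",
            f"retained down features:  {len(self.down)}",
            f"profile features:        {len(self.profile.feature_ids)}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write up.tsv, down.tsv and profile.tsv under ``out_dir``."""
        from .io import write_outlier_table

        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_outlier_table(self.up, out / "up.tsv", "up")
        write_outlier_table(self.down, out / "down.tsv", "down")
        self.profile.to_tsv(out / "profile.tsv")
        logger.info("results written to %s", out)
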