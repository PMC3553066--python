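"""Expression-matrix container.

The whole pipeline operates on a features x samples grid of log2-scale
normalised intensities in which the leading ``n_normal`` columns are the
normal/control samples and the remaining columns are tumour samples.  When an
experiment has no true normals, a chosen subset of case samples placed first
plays the role of the control group; the container therefore names the two
groups "control" and "case" internally but keeps the conventional
normal/tumour vocabulary in its API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Feature x sample grid with a leading block of normal/control columns.

    Parameters
    ----------
    values
        DataFrame, rows = features, columns = samples.  May contain NaN before
        preprocessing; downstream steps require a fully observed matrix.
    n_normal
        Number of leading columns forming the normal (control) group.
        Must satisfy ``1 <= n_normal < n_samples``.
    """

    values: pd.DataFrame
    n_normal: int

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        n_samples = self.values.shape[1]
        if not 1 <= self.n_normal:
            raise ValueError(f"n_normal must be >= 1, got {self.n_normal}")
        if self.n_normal >= n_samples:
            raise ValueError(
                f"no tumour samples: n_normal={self.n_normal} but matrix has "
                f"{n_samples} sample columns"
            )

    # -- identifiers ------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def normal_ids(self) -> pd.Index:
        return self.values.columns[: self.n_normal]

    @property
    def tumour_ids(self) -> pd.Index:
        return self.values.columns[self.n_normal :]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_tumour(self) -> int:
        return self.n_samples - self.n_normal

    # -- views ------------------------------------------------------------
    @property
    def normal_values(self) -> pd.DataFrame:
        return self.values.iloc[:, : self.n_normal]

    @property
    def tumour_values(self) -> pd.DataFrame:
        return self.values.iloc[:, self.n_normal :]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[feature_ids], self.n_normal)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.n_normal)

    # -- io (thin wrappers; see mcopa.io) ---------------------------------
    @classmethod
    def from_tsv(cls, path, n_normal: int) -> "ExpressionMatrix":
        from .io import read_matrix

        return read_matrix(path, n_normal)

    def to_tsv(self, path) -> None:
        from .io import write_matrix

        write_matrix(self, path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_features} features x {self.n_samples} samples; "
            f"{self.n_normal} normal, {self.n_tumour} tumour)"
        )
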