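"""Outlier profiles: per-feature codes over samples and their summaries.

A profile row is a sequence over all samples with 1 (over-expressed outlier),
-1 (under-expressed outlier) or 0 (neither).  Only features that survived
filtering in at least one direction appear.  Profiles support extraction of
subtype-exclusive outliers, per-sample outlier lists, and histograms of how
many samples share each outlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OutlierProfile",
    "build_profiles",
    "subtype_outliers",
    "sample_outlier_lists",
    "sharing_histogram",
]


@dataclass
class OutlierProfile:
    """Dense per-(feature, sample) code table restricted to {1, -1, 0}."""

    codes: pd.DataFrame  # features x samples, int8

    def __post_init__(self) -> None:
        vals = self.codes.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("profile codes must be in {1, -1, 0}")
        self.codes = self.codes.astype(np.int8)

    @property
    def feature_ids(self) -> pd.Index:
        return self.codes.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.codes.columns

    def strings(self) -> pd.Series:
        """Compact comma-separated string form, one string per feature."""
        return pd.Series(
            [",".join(str(v) for v in row) for row in self.codes.to_numpy()],
            index=self.codes.index,
            name="profile",
        )

    def to_tsv(self, path) -> None:
        out = self.codes.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "OutlierProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def plot_sharing(self, selection=None, ax=None):
        """Bar plot of the outlier-sharing histogram (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if selection is None:
            selection = list(self.sample_ids)
        hist, outside = sharing_histogram(self, selection)
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(hist.index, hist.to_numpy(), color="steelblue")
        ax.set_xlabel("number of selected samples sharing the outlier")
        ax.set_ylabel("outlier features")
        ax.set_title(f"outlier sharing ({outside} features only outside selection)")
        return ax


def build_profiles(
    up_table: pd.DataFrame,
    down_table: pd.DataFrame,
    sample_ids: Sequence[str],
) -> OutlierProfile:
    """Merge directional outlier tables into one code per (feature, sample).

    Tables are as produced by the filter: indexed by feature id with an
    ``outlier_samples`` column listing tumour samples.  A feature present in
    both tables contributes both 1 and -1 codes; the same (feature, sample)
    cell claimed in both directions is impossible for calls derived from
    ordered fences and raises.
    """
    sample_ids = pd.Index(sample_ids)
    features = up_table.index.union(down_table.index, sort=False)
    codes = pd.DataFrame(
        np.zeros((len(features), len(sample_ids)), dtype=np.int8),
        index=features,
        columns=sample_ids,
    )
    for table, code in ((up_table, 1), (down_table, -1)):
        for feat, samples in table["outlier_samples"].items():
            for s in samples:
                if s not in codes.columns:
                    raise ValueError(f"sample {s!r} in table is not among sample_ids")
                if codes.at[feat, s] == -code:
                    raise ValueError(
                        f"conflicting up/down call at feature {feat!r}, sample {s!r}"
                    )
                codes.at[feat, s] = code
    codes.index.name = "feature_id"
    return OutlierProfile(codes)


def _direction_mask(profile: OutlierProfile, direction: str) -> pd.DataFrame:
    if direction == "up":
        return profile.codes.eq(1)
    if direction == "down":
        return profile.codes.eq(-1)
    if direction == "both":
        return profile.codes.ne(0)
    raise ValueError(f"direction must be 'up', 'down' or 'both', got {direction!r}")


def _check_selection(profile: OutlierProfile, subtype_samples: Iterable[str]) -> list:
    sel = list(subtype_samples)
    if not sel:
        raise ValueError("subtype selection is empty")
    unknown = [s for s in sel if s not in profile.sample_ids]
    if unknown:
        raise ValueError(f"unknown sample ids in selection: {unknown[:5]}")
    return sel


def subtype_outliers(
    profile: OutlierProfile,
    subtype_samples: Iterable[str],
    direction: str = "both",
    exclusive: bool = True,
) -> list:
    """Features whose outlier calls fall within a nominated sample set.

    With ``exclusive=True`` (default) a feature is returned when all of its
    nonzero codes of the given direction lie inside the selection and at least
    one does; with ``exclusive=False``, when at least one does.
    """
    sel = _check_selection(profile, subtype_samples)
    mask = _direction_mask(profile, direction)
    inside = mask[sel].any(axis=1)
    if exclusive:
        outside_cols = [s for s in profile.sample_ids if s not in set(sel)]
        outside = mask[outside_cols].any(axis=1)
        keep = inside & ~outside
    else:
        keep = inside
    return list(profile.feature_ids[keep])


def sample_outlier_lists(profile: OutlierProfile) -> pd.DataFrame:
    """Invert the profile: per-sample lists of up and down outlier features.

    Returns a DataFrame indexed by sample id with columns ``up``, ``down``
    (lists of feature ids) and their counts.
    """
    up = {
        s: list(profile.feature_ids[profile.codes[s] == 1]) for s in profile.sample_ids
    }
    down = {
        s: list(profile.feature_ids[profile.codes[s] == -1]) for s in profile.sample_ids
    }
    out = pd.DataFrame(
        {
            "up": pd.Series(up),
            "down": pd.Series(down),
        }
    )
    out["n_up"] = out["up"].map(len)
    out["n_down"] = out["down"].map(len)
    out.index.name = "sample_id"
    return out


def sharing_histogram(
    profile: OutlierProfile,
    subtype_samples: Iterable[str],
    direction: str = "both",
):
    """Distribution of how many selected samples share each outlier feature.

    Considers features with at least one nonzero code (of the requested
    direction) inside the selection; the histogram is over k = number of
    selected samples in which the feature is an outlier.  Also returns the
    count of features whose outlier codes all fall outside the selection.

    Returns
    -------
    (hist, n_outside)
        ``hist``: Series indexed by k (1..max) with feature counts;
        ``n_outside``: features with outlier codes only outside the selection.
    """
    sel = _check_selection(profile, subtype_samples)
    mask = _direction_mask(profile, direction)
    k = mask[sel].sum(axis=1)
    has_any = mask.any(axis=1)
    inside = k > 0
    n_outside = int((has_any & ~inside).sum())
    counts = k[inside].value_counts().sort_index()
    counts.index.name = "n_samples_sharing"
    counts.name = "n_features"
    return counts, n_outside
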