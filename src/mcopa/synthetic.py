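"""Synthetic expression matrices with planted ground truth.

The generator emulates a log2-scale normalised matrix with a normal group and
a tumour group split into subtypes, and four kinds of planted feature:

- ``outlier_up`` / ``outlier_down``: background plus a +/-delta shift in a
  small seeded subset of tumour samples (the regime of transcripts extreme in
  only a few cancers).  A configurable fraction is subtype-specific: the
  affected samples are drawn from a single subtype, recurrently (a feature
  present in a meaningful share of the subtype can define it; one touching a
  single sample cannot).
- ``de``: all tumour samples shifted by ``de_delta`` (classical differential
  expression).
- ``noise``: high-variance features with no group structure, the classical
  trap for variance-based selection.
- ``background``: i.i.d. noise around a per-feature baseline.

Each feature draws from its own counter-derived substream of the master seed,
so enlarging the matrix leaves existing features' values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["SimulationConfig", "GroundTruth", "generate", "score_recovery"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Scales are log2 expression units throughout.  Defaults describe a small
    two-condition array study: 2000 features, 10 normal and 20 tumour samples
    in two subtypes of 10; measurement noise 0.5; 200 outlier features (shift
    4.0 in 10% of the tumour group, half of them subtype-specific and
    recurrent in 30% of their subtype); 100 differentially expressed features
    (shift 2.0 in all tumours); 100 high-variance noise features (SD 2.0).
    """

    n_features: int = 2000
    n_normal: int = 10
    n_tumour: int = 20
    subtype_sizes: Tuple[int, ...] = (10, 10)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5
    n_outlier_features: int = 200
    outlier_delta: float = 4.0
    outlier_sample_fraction: float = 0.1
    outlier_direction_mix: float = 0.5
    subtype_specific_fraction: float = 0.5
    subtype_sample_fraction: float = 0.3
    n_de_features: int = 100
    de_delta: float = 2.0
    n_noise_features: int = 100
    noise_feature_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.n_normal, self.n_tumour) < 1:
            raise ValueError("n_features, n_normal and n_tumour must be positive")
        if sum(self.subtype_sizes) != self.n_tumour:
            raise ValueError(
                f"subtype_sizes {self.subtype_sizes} must sum to n_tumour={self.n_tumour}"
            )
        if any(s < 1 for s in self.subtype_sizes):
            raise ValueError("subtype sizes must be positive")
        for name in ("outlier_sample_fraction", "subtype_sample_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.outlier_direction_mix <= 1.0:
            raise ValueError("outlier_direction_mix must be in [0, 1]")
        if not 0.0 <= self.subtype_specific_fraction <= 1.0:
            raise ValueError("subtype_specific_fraction must be in [0, 1]")
        planted = self.n_outlier_features + self.n_de_features + self.n_noise_features
        if planted > self.n_features:
            raise ValueError(
                f"planted features ({planted}) exceed n_features ({self.n_features})"
            )
        if self.noise_sd <= 0 or self.noise_feature_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.n_outlier_features > 0:
            if round(self.outlier_sample_fraction * self.n_tumour) < 1:
                raise ValueError(
                    "infeasible config: outlier_sample_fraction rounds to zero "
                    f"affected samples ({self.outlier_sample_fraction} of "
                    f"{self.n_tumour} tumours)"
                )
            if self.subtype_specific_fraction > 0 and any(
                round(self.subtype_sample_fraction * s) < 1 for s in self.subtype_sizes
            ):
                raise ValueError(
                    "infeasible config: subtype_sample_fraction rounds to zero "
                    "affected samples in some subtype"
                )


@dataclass
class GroundTruth:
    """Planted feature classes: one row per feature.

    ``table`` columns: ``feature_class`` in {background, outlier_up,
    outlier_down, de, noise}; ``affected_samples`` (list of sample ids, empty
    for background/noise); ``subtype`` (label or ``""``).
    """

    table: pd.DataFrame

    def features_of(self, feature_class: str) -> pd.Index:
        return self.table.index[self.table["feature_class"] == feature_class]

    def affected(self, feature_id) -> list:
        return self.table.at[feature_id, "affected_samples"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["affected_samples"] = out["affected_samples"].map(",".join)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        df["affected_samples"] = [
            s.split(",") if s else [] for s in df["affected_samples"]
        ]
        return cls(df)


def _feature_rng(seed: int, index: int) -> np.random.Generator:
    # counter-derived substream: feature i always sees the same draws
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate(config: Optional[SimulationConfig] = None, **overrides) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Simulate an expression matrix and its planted truth.

    Keyword overrides build a fresh :class:`SimulationConfig`, e.g.
    ``generate(seed=3, n_de_features=0)``.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    c = config

    n_samples = c.n_normal + c.n_tumour
    width = len(str(c.n_features))
    feature_ids = [f"f{str(i + 1).zfill(width)}" for i in range(c.n_features)]
    sample_ids = [f"N{i + 1}" for i in range(c.n_normal)]
    subtype_of = {}
    si = 0
    for st, size in enumerate(c.subtype_sizes):
        for _ in range(size):
            sid = f"T{si + 1}"
            subtype_of[sid] = f"S{st + 1}"
            sample_ids.append(sid)
            si += 1
    tumour_ids = sample_ids[c.n_normal :]
    subtype_members = {
        st: [s for s in tumour_ids if subtype_of[s] == st]
        for st in sorted(set(subtype_of.values()))
    }
    subtype_names = sorted(subtype_members)

    n_up = round(c.n_outlier_features * c.outlier_direction_mix)
    x = np.empty((c.n_features, n_samples))
    classes = []
    affected_lists = []
    subtypes = []

    for i in range(c.n_features):
        rng = _feature_rng(c.seed, i)
        baseline = rng.normal(c.baseline_mean, c.baseline_sd)
        if i < c.n_outlier_features:
            cls = "outlier_up" if i < n_up else "outlier_down"
            sign = 1.0 if cls == "outlier_up" else -1.0
            row = baseline + rng.normal(0.0, c.noise_sd, n_samples)
            subtype_specific = rng.random() < c.subtype_specific_fraction
            if subtype_specific:
                st = subtype_names[rng.integers(len(subtype_names))]
                pool = subtype_members[st]
                m = round(c.subtype_sample_fraction * len(pool))
            else:
                st = ""
                pool = tumour_ids
                m = round(c.outlier_sample_fraction * len(pool))
            m = min(max(m, 1), len(pool))
            chosen = sorted(rng.choice(len(pool), m, replace=False))
            affected = [pool[j] for j in chosen]
            for s in affected:
                row[sample_ids.index(s)] += sign * c.outlier_delta
            classes.append(cls)
            affected_lists.append(affected)
            subtypes.append(st)
        elif i < c.n_outlier_features + c.n_de_features:
            row = baseline + rng.normal(0.0, c.noise_sd, n_samples)
            row[c.n_normal :] += c.de_delta
            classes.append("de")
            affected_lists.append(list(tumour_ids))
            subtypes.append("")
        elif i < c.n_outlier_features + c.n_de_features + c.n_noise_features:
            row = baseline + rng.normal(0.0, c.noise_feature_sd, n_samples)
            classes.append("noise")
            affected_lists.append([])
            subtypes.append("")
        else:
            row = baseline + rng.normal(0.0, c.noise_sd, n_samples)
            classes.append("background")
            affected_lists.append([])
            subtypes.append("")
        x[i] = row

    values = pd.DataFrame(x, index=feature_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values, c.n_normal)
    truth = pd.DataFrame(
        {
            "feature_class": classes,
            "affected_samples": affected_lists,
            "subtype": subtypes,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return matrix, GroundTruth(truth)


def subtype_labels(config: SimulationConfig) -> pd.Series:
    """Tumour sample -> subtype label Series matching :func:`generate`."""
    labels = {}
    si = 0
    for st, size in enumerate(config.subtype_sizes):
        for _ in range(size):
            labels[f"T{si + 1}"] = f"S{st + 1}"
            si += 1
    s = pd.Series(labels, name="subtype")
    s.index.name = "sample_id"
    return s


def score_recovery(
    truth: GroundTruth,
    up_table: pd.DataFrame,
    down_table: pd.DataFrame,
) -> pd.DataFrame:
    """Precision/recall of outlier calls against the planted truth.

    Scored per direction at two granularities:

    - feature level: a retained feature counts as a true positive when the
      planted class matches the direction;
    - sample level: a (feature, sample) pair counts when the sample is among
      the feature's planted affected samples.

    With no calls, precision is reported as 1.0 by convention (no false
    claims were made) and recall as 0 when truth is non-empty.
    """
    rows = []
    for direction, table in (("up", up_table), ("down", down_table)):
        cls = f"outlier_{direction}"
        true_feats = set(truth.features_of(cls))
        called_feats = set(table.index)
        tp = len(true_feats & called_feats)
        feat_prec = tp / len(called_feats) if called_feats else 1.0
        feat_rec = tp / len(true_feats) if true_feats else 1.0

        true_pairs = {
            (f, s) for f in true_feats for s in truth.affected(f)
        }
        called_pairs = {
            (f, s) for f, samples in table["outlier_samples"].items() for s in samples
        }
        ptp = len(true_pairs & called_pairs)
        pair_prec = ptp / len(called_pairs) if called_pairs else 1.0
        pair_rec = ptp / len(true_pairs) if true_pairs else 1.0
        rows.append(
            {
                "direction": direction,
                "feature_precision": feat_prec,
                "feature_recall": feat_rec,
                "sample_precision": pair_prec,
                "sample_recall": pair_rec,
                "n_true_features": len(true_feats),
                "n_called_features": len(called_feats),
            }
        )
    return pd.DataFrame(rows).set_index("direction")
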