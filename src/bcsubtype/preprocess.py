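"""Probeset collapsing and robust percentile scaling.

Cross-dataset comparability of Affymetrix-style log2 intensities is obtained
by a robust per-feature affine rescaling within each dataset: the 2.5th and
97.5th percentiles of every feature are mapped to -1 and +1. Percentiles use
linear interpolation between the closest order statistics (the "type 7"
convention); values outside the two anchors map outside [-1, +1] without
clipping, and constant features map to 0.

Cohorts with a heavily skewed subtype distribution are scaled pooled with an
anchor cohort: parameters are fitted on the column-wise concatenation of the
two, applied to the target only, and the anchor is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import ExpressionMatrix, GeneMapping

__all__ = [
    "RobustPercentileScaler",
    "ScalingParams",
    "collapse_probesets",
    "fit_robust_scaling",
    "apply_robust_scaling",
    "robust_scale",
    "pooled_scale",
]


class RobustPercentileScaler(BaseEstimator, TransformerMixin):
    """Map per-feature percentiles ``(q_low, q_high)`` to ``(-1, +1)``.

    Follows the sklearn transformer protocol on samples x features input.

    Parameters
    ----------
    lower, upper : percentile anchors in [0, 100]; defaults 2.5 and 97.5.

    Attributes
    ----------
    q_low_, q_high_ : ndarray of shape (n_features,)
        Fitted percentile values per feature.
    feature_names_in_ : ndarray of column names when fitted on a DataFrame.
    """

    def __init__(self, lower: float = 2.5, upper: float = 97.5):
        self.lower = lower
        self.upper = upper

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x features array")
        if X.shape[0] < 2:
            raise ValueError(
                "cannot estimate percentiles from fewer than 2 samples"
            )
        # 'linear' = interpolation between closest order statistics (type 7)
        self.q_low_ = np.percentile(X, self.lower, axis=0, method="linear")
        self.q_high_ = np.percentile(X, self.upper, axis=0, method="linear")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "q_low_")
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; scaler fitted on {self.n_features_in_}"
            )
        span = self.q_high_ - self.q_low_
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = 2.0 * (X[:, ok] - self.q_low_[ok]) / span[ok] - 1.0
        # constant features (q_low == q_high) map to 0
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature robust scaling anchors (2.5th / 97.5th percentile values)."""

    q_low: pd.Series
    q_high: pd.Series

    def __post_init__(self) -> None:
        if not self.q_low.index.equals(self.q_high.index):
            raise ValueError("q_low and q_high must share a feature index")
        if (self.q_low > self.q_high).any():
            bad = self.q_low.index[self.q_low > self.q_high].tolist()
            raise ValueError(f"q_low > q_high for features: {bad[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.q_low.index)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"feature_id": self.q_low.index, "q_low": self.q_low.values,
             "q_high": self.q_high.values}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ScalingParams":
        df = pd.read_csv(path, sep="\t").set_index("feature_id")
        return cls(q_low=df["q_low"], q_high=df["q_high"])


def collapse_probesets(m: ExpressionMatrix, mapping: GeneMapping) -> ExpressionMatrix:
    """Collapse a probeset-level matrix to gene level.

    When multiple probesets map to the same gene identifier the most
    variable probeset (largest sample variance across this dataset) is
    retained; ties are broken toward the lexicographically smaller probeset
    id. Unmapped probesets are dropped. The chosen probeset per gene is
    recorded under ``meta["chosen_probeset"]``.
    """
    if m.level != "probeset":
        if m.level == "gene":
            # idempotent on gene-level input
            return m
        raise ValueError(f"unknown matrix level {m.level!r}")
    mapped = [(f, mapping.gene_of(f)) for f in m.feature_ids]
    mapped = [(f, g) for f, g in mapped if g is not None]
    if not mapped:
        raise ValueError("no features mappable: mapping covers none of the probesets")
    df = m.to_frame()
    variances = df.var(axis=1, ddof=1)
    by_gene: dict[str, list[str]] = {}
    for f, g in mapped:
        by_gene.setdefault(g, []).append(f)
    chosen: dict[str, str] = {}
    for g, probes in by_gene.items():
        # max variance; tie -> lexicographically smaller probeset id
        chosen[g] = min(probes, key=lambda p: (-variances[p], p))
    genes = sorted(chosen)
    out = df.loc[[chosen[g] for g in genes]]
    out.index = genes
    meta = dict(m.meta)
    meta["chosen_probeset"] = dict(chosen)
    return ExpressionMatrix.from_frame(
        out, dataset_id=m.dataset_id, level="gene", scaled=m.scaled, meta=meta
    )


def fit_robust_scaling(m: ExpressionMatrix) -> ScalingParams:
    """Fit per-feature 2.5/97.5 percentile anchors within one dataset."""
    if m.n_samples < 2:
        raise ValueError(
            f"cannot estimate percentiles: dataset {m.dataset_id!r} has "
            f"{m.n_samples} sample(s)"
        )
    scaler = RobustPercentileScaler().fit(m.to_frame().T)
    idx = pd.Index(m.feature_ids)
    return ScalingParams(
        q_low=pd.Series(scaler.q_low_, index=idx),
        q_high=pd.Series(scaler.q_high_, index=idx),
    )


def apply_robust_scaling(m: ExpressionMatrix, p: ScalingParams) -> ExpressionMatrix:
    """Apply fitted anchors: x' = 2 (x - q_low) / (q_high - q_low) - 1."""
    missing = [f for f in m.feature_ids if f not in p.q_low.index]
    if missing:
        raise ValueError(f"features missing from scaling params: {missing[:10]}")
    ql = p.q_low.loc[m.feature_ids].to_numpy()
    qh = p.q_high.loc[m.feature_ids].to_numpy()
    span = qh - ql
    out = np.zeros_like(m.values, dtype=float)
    ok = span > 0
    out[ok, :] = 2.0 * (m.values[ok, :] - ql[ok, None]) / span[ok, None] - 1.0
    return ExpressionMatrix(
        feature_ids=list(m.feature_ids),
        sample_ids=list(m.sample_ids),
        values=out,
        dataset_id=m.dataset_id,
        level=m.level,
        scaled=True,
        meta=dict(m.meta),
    )


def robust_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convenience: fit and apply robust scaling within one dataset."""
    return apply_robust_scaling(m, fit_robust_scaling(m))


def pooled_scale(target: ExpressionMatrix, anchor: ExpressionMatrix) -> ExpressionMatrix:
    """Scale a skewed cohort pooled with an anchor cohort.

    Anchors are fitted on the column-wise concatenation [target | anchor],
    applied to the target only; the anchor columns are discarded. With an
    empty anchor this reduces to plain fit+apply on the target.
    """
    if anchor.n_samples == 0:
        return robust_scale(target)
    tset, aset = set(target.feature_ids), set(anchor.feature_ids)
    if tset != aset:
        diff = sorted(tset.symmetric_difference(aset))
        raise ValueError(f"feature spaces disagree; symmetric difference: {diff[:10]}")
    adf = anchor.to_frame().loc[target.feature_ids]
    pooled = pd.concat([target.to_frame(), adf], axis=1)
    pooled_m = ExpressionMatrix.from_frame(
        pooled, dataset_id=target.dataset_id, level=target.level
    )
    params = fit_robust_scaling(pooled_m)
    return apply_robust_scaling(target, params)
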