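"""Single sample predictor (SSP): nearest-centroid subtype classification.

For each subtype a centroid is the per-gene mean of robustly scaled
expression over labeled training samples, restricted to an intrinsic gene
list (IGL). A new case is assigned to the subtype whose centroid is nearest
under a configurable metric; the default is Spearman distance
(1 - Spearman correlation), which makes predictions invariant to any
strictly monotone per-sample transform of expression. Distance ties are
broken by the canonical subtype order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .core import SUBTYPE_ORDER, ExpressionMatrix, GeneListSet, Subtype, SubtypeAssignment

__all__ = ["SSPClassifier", "SSPModel", "train_ssp", "predict_ssp"]

_METRICS = ("spearman", "pearson", "euclidean")


def _correlation_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    an = np.linalg.norm(Az, axis=1)
    bn = np.linalg.norm(Bz, axis=1)
    # constant rows have undefined correlation; treat as 0 (max distance 1)
    an[an == 0] = np.inf
    bn[bn == 0] = np.inf
    return (Az / an[:, None]) @ (Bz / bn[:, None]).T


class SSPClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier over gene expression profiles.

    Parameters
    ----------
    metric : {"spearman", "pearson", "euclidean"}
        Distance between a sample and a centroid; correlation metrics use
        distance = 1 - correlation.
    min_class_size : minimum number of training samples per subtype.

    Attributes
    ----------
    classes_ : subtypes seen in training, in canonical order.
    centroids_ : DataFrame (subtype x gene) of per-gene class means.
    feature_names_in_ : gene identifiers the classifier was fitted on.
    """

    def __init__(self, metric: str = "spearman", min_class_size: int = 5):
        self.metric = metric
        self.min_class_size = min_class_size

    def fit(self, X: pd.DataFrame, y):
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}, got {self.metric!r}")
        X = pd.DataFrame(X)
        y = pd.Series([Subtype(v) for v in y], index=X.index)
        counts = y.value_counts()
        for s, n in counts.items():
            if n < self.min_class_size:
                raise ValueError(
                    f"subtype {Subtype(s).value} has {n} training samples, "
                    f"fewer than min_class_size={self.min_class_size}"
                )
        self.classes_ = np.array(
            [s for s in SUBTYPE_ORDER if s in set(y)], dtype=object
        )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.centroids_ = pd.DataFrame(
            {s.value: X.loc[list(y[y == s].index)].mean(axis=0) for s in self.classes_}
        ).T
        return self

    def _distances(self, X: pd.DataFrame) -> np.ndarray:
        C = self.centroids_.to_numpy()
        Xv = X.to_numpy(dtype=float)
        if self.metric == "euclidean":
            return cdist(Xv, C)
        if self.metric == "pearson":
            return 1.0 - _correlation_rows(Xv, C)
        R = rankdata(Xv, axis=1)
        CR = rankdata(C, axis=1)
        return 1.0 - _correlation_rows(R, CR)

    def decision_distances(self, X: pd.DataFrame) -> pd.DataFrame:
        """Distance of every sample to every class centroid."""
        check_is_fitted(self, "centroids_")
        X = self._check_X(X)
        return pd.DataFrame(
            self._distances(X), index=X.index, columns=[s.value for s in self.classes_]
        )

    def _check_X(self, X, allow_intersection: bool = False, min_genes: int = 3):
        X = pd.DataFrame(X)
        wanted = list(self.feature_names_in_)
        missing = [g for g in wanted if g not in X.columns]
        if missing and not allow_intersection:
            raise ValueError(
                f"{len(missing)} model genes missing from data, e.g. {missing[:5]}; "
                "pass allow_intersection=True to predict on the intersection"
            )
        if missing:
            common = [g for g in wanted if g in X.columns]
            if len(common) < min_genes:
                raise ValueError(
                    f"only {len(common)} genes in common; need at least {min_genes}"
                )
            self._last_n_genes_ = len(common)
            return X[common]
        self._last_n_genes_ = len(wanted)
        return X[wanted]

    def predict(self, X, allow_intersection: bool = False):
        check_is_fitted(self, "centroids_")
        Xc = self._check_X(X, allow_intersection=allow_intersection)
        if Xc.shape[1] != len(self.feature_names_in_):
            C = self.centroids_[Xc.columns]
            tmp = SSPClassifier(metric=self.metric)
            tmp.classes_, tmp.centroids_ = self.classes_, C
            tmp.feature_names_in_ = np.asarray(Xc.columns, dtype=object)
            d = tmp._distances(Xc)
        else:
            d = self._distances(Xc)
        # argmin takes the first minimum; classes_ is in canonical order
        return self.classes_[np.argmin(d, axis=1)]


@dataclass(frozen=True)
class SSPModel:
    """Serializable fitted SSP: centroids over an IGL plus the metric."""

    igl_id: str
    gene_ids: tuple[str, ...]
    centroids: dict  # subtype value -> list of floats over gene_ids
    metric: str = "spearman"
    training_set_id: str = ""

    def __post_init__(self) -> None:
        for s, vec in self.centroids.items():
            Subtype(s)
            if len(vec) != len(self.gene_ids):
                raise ValueError(
                    f"centroid {s} has {len(vec)} values for {len(self.gene_ids)} genes"
                )

    def to_classifier(self) -> SSPClassifier:
        clf = SSPClassifier(metric=self.metric)
        order = [s for s in SUBTYPE_ORDER if s.value in self.centroids]
        clf.classes_ = np.array(order, dtype=object)
        clf.feature_names_in_ = np.asarray(self.gene_ids, dtype=object)
        clf.centroids_ = pd.DataFrame(
            [self.centroids[s.value] for s in order],
            index=[s.value for s in order],
            columns=list(self.gene_ids),
        )
        return clf

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model_type": "SSP",
                    "igl_id": self.igl_id,
                    "metric": self.metric,
                    "training_set_id": self.training_set_id,
                    "gene_ids": list(self.gene_ids),
                    "centroids": {k: list(map(float, v)) for k, v in self.centroids.items()},
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path, drop_unknown_subtypes: bool = True) -> "SSPModel":
        """Load a model; centroids for labels outside the 4-subtype
        vocabulary (e.g. a normal-like centroid of a 5-class reference
        predictor) are dropped when ``drop_unknown_subtypes`` is set."""
        with open(path) as fh:
            d = json.load(fh)
        centroids = dict(d["centroids"])
        known = {s.value for s in Subtype}
        unknown = [k for k in centroids if k not in known]
        if unknown:
            if not drop_unknown_subtypes:
                raise ValueError(f"unknown subtype centroids: {unknown}")
            for k in unknown:
                centroids.pop(k)
        return cls(
            igl_id=d["igl_id"],
            gene_ids=tuple(d["gene_ids"]),
            centroids=centroids,
            metric=d.get("metric", "spearman"),
            training_set_id=d.get("training_set_id", ""),
        )


def train_ssp(
    m: ExpressionMatrix,
    labels: SubtypeAssignment,
    igl: GeneListSet,
    metric: str = "spearman",
    min_class_size: int = 5,
) -> SSPModel:
    """Estimate per-subtype centroids on scaled expression over an IGL."""
    if igl.kind != "IGL":
        raise ValueError(f"gene list {igl.list_id!r} is not an IGL")
    if not m.scaled:
        raise ValueError("SSP training requires robustly scaled expression")
    genes = [g for g in igl.genes if g in set(m.feature_ids)]
    if not genes:
        raise ValueError(f"IGL {igl.list_id!r} shares no genes with the data")
    X = m.to_frame().loc[genes].T
    y = labels.reindex(m.sample_ids).to_series()
    clf = SSPClassifier(metric=metric, min_class_size=min_class_size).fit(X, y)
    return SSPModel(
        igl_id=igl.list_id,
        gene_ids=tuple(genes),
        centroids={s.value: clf.centroids_.loc[s.value].tolist() for s in clf.classes_},
        metric=metric,
        training_set_id=m.dataset_id,
    )


def predict_ssp(
    model: SSPModel,
    m: ExpressionMatrix,
    allow_intersection: bool = False,
    predictor_id: str | None = None,
) -> SubtypeAssignment:
    """Assign each sample to the subtype of its nearest centroid."""
    if not m.scaled:
        raise ValueError("SSP prediction requires robustly scaled expression")
    clf = model.to_classifier()
    X = m.to_frame().T
    labels = clf.predict(X, allow_intersection=allow_intersection)
    pid = predictor_id or f"SSP.{model.igl_id}.{model.training_set_id}"
    return SubtypeAssignment(
        sample_ids=tuple(m.sample_ids), labels=tuple(labels), predictor_id=pid
    )
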