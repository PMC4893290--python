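"""Subtype classification model (SCM).

Training samples are represented by robustly scaled module scores. A
3-component full-covariance bivariate Gaussian mixture is fitted to the
(ER, HER2) scores and its components are labeled basal / HER2 / luminal by
their means: the component with the largest ER mean is luminal; of the
remaining two, the one with the largest HER2 mean is HER2 and the last is
basal. Luminal samples are then split into luminal A (low proliferation)
and luminal B (high proliferation) by a univariate 2-component mixture
fitted on the proliferation scores of the luminal training samples.

Prediction computes the posterior membership probabilities under the fitted
mixtures and selects the subtype with maximum posterior; exact ties break
toward the canonical subtype order (and toward luminal A at the
equal-posterior proliferation point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .core import Subtype, SubtypeAssignment
from .modules import ModuleScoreMatrix

__all__ = ["SCMClassifier", "SCMModel", "fit_scm", "predict_scm"]

_COMPONENT_ORDER = ("BASAL", "HER2", "LUMINAL")


def _make_gmm_2d(weights, means, covariances) -> GaussianMixture:
    """Rebuild a frozen sklearn GaussianMixture from parameter arrays."""
    gmm = GaussianMixture(n_components=len(weights), covariance_type="full")
    gmm.weights_ = np.asarray(weights, dtype=float)
    gmm.means_ = np.asarray(means, dtype=float)
    gmm.covariances_ = np.asarray(covariances, dtype=float)
    from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

    gmm.precisions_cholesky_ = _compute_precision_cholesky(gmm.covariances_, "full")
    return gmm


class SCMClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian-mixture subtype classifier on (ER, HER2, PROLIF) scores.

    Fitting is unsupervised: ``fit(X)`` expects a DataFrame with at least
    the columns ``ER``, ``HER2`` and ``PROLIF`` holding scaled module
    scores.

    Parameters
    ----------
    n_restarts : EM restarts (best log-likelihood kept).
    tol : EM convergence tolerance.
    luminal_split : "mixture" (2-component EM posterior on PROLIF) or
        "threshold" (fixed cutpoint, default 0).
    prolif_threshold : cutpoint used in threshold mode.
    min_luminal : minimum number of luminal training samples.
    max_condition : covariance condition-number bound beyond which the fit
        is reported as degenerate.
    random_state : seed controlling all restarts.
    """

    def __init__(
        self,
        n_restarts: int = 10,
        tol: float = 1e-6,
        luminal_split: str = "mixture",
        prolif_threshold: float = 0.0,
        min_luminal: int = 10,
        min_samples: int = 30,
        max_condition: float = 1e8,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.tol = tol
        self.luminal_split = luminal_split
        self.prolif_threshold = prolif_threshold
        self.min_luminal = min_luminal
        self.min_samples = min_samples
        self.max_condition = max_condition
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        for col in ("ER", "HER2", "PROLIF"):
            if col not in X.columns:
                raise ValueError(f"score matrix lacks required module column {col!r}")
        if len(X) < self.min_samples:
            raise ValueError(
                f"SCM fitting requires >= {self.min_samples} samples, got {len(X)}"
            )
        Z = X[["ER", "HER2"]].to_numpy(dtype=float)
        gmm = GaussianMixture(
            n_components=3,
            covariance_type="full",
            n_init=self.n_restarts,
            init_params="k-means++",
            tol=self.tol,
            random_state=self.random_state,
            reg_covar=1e-8,
        ).fit(Z)
        for k, cov in enumerate(gmm.covariances_):
            cond = np.linalg.cond(cov)
            if not np.isfinite(cond) or cond > self.max_condition:
                raise ValueError(
                    f"degenerate mixture component {k}: covariance condition "
                    f"number {cond:.3g} exceeds bound {self.max_condition:.3g}"
                )
        # label components by their means: luminal = max ER mean, then
        # HER2 = max HER2 mean of the rest, basal = the remaining one
        lum = int(np.argmax(gmm.means_[:, 0]))
        rest = [k for k in range(3) if k != lum]
        her2 = rest[int(np.argmax(gmm.means_[rest, 1]))]
        basal = next(k for k in rest if k != her2)
        self.comp_map_ = {basal: "BASAL", her2: "HER2", lum: "LUMINAL"}
        self.gmm_ = gmm
        # proliferation split on luminal training samples
        resp = gmm.predict_proba(Z)
        lum_mask = np.argmax(resp, axis=1) == lum
        n_lum = int(lum_mask.sum())
        if n_lum < self.min_luminal:
            raise ValueError(
                f"only {n_lum} luminal training samples; need >= {self.min_luminal}"
            )
        p = X.loc[lum_mask, "PROLIF"].to_numpy(dtype=float).reshape(-1, 1)
        pg = GaussianMixture(
            n_components=2,
            n_init=self.n_restarts,
            init_params="k-means++",
            tol=self.tol,
            random_state=self.random_state,
            reg_covar=1e-8,
        ).fit(p)
        low = int(np.argmin(pg.means_[:, 0]))
        self.prolif_split_ = {
            "pi_low": float(pg.weights_[low]),
            "mu_low": float(pg.means_[low, 0]),
            "sigma_low": float(np.sqrt(pg.covariances_[low].ravel()[0])),
            "mu_high": float(pg.means_[1 - low, 0]),
            "sigma_high": float(np.sqrt(pg.covariances_[1 - low].ravel()[0])),
        }
        self.classes_ = np.array(
            [Subtype.BASAL, Subtype.HER2, Subtype.LUMA, Subtype.LUMB], dtype=object
        )
        return self

    # -- posterior machinery ----------------------------------------------
    def component_posterior(self, X: pd.DataFrame) -> pd.DataFrame:
        """Posterior over the basal/HER2/luminal components per sample."""
        check_is_fitted(self, "gmm_")
        X = pd.DataFrame(X)
        for col in ("ER", "HER2"):
            if col not in X.columns:
                raise ValueError(f"score matrix lacks required module column {col!r}")
        resp = self.gmm_.predict_proba(X[["ER", "HER2"]].to_numpy(dtype=float))
        cols = {self.comp_map_[k]: resp[:, k] for k in range(3)}
        return pd.DataFrame(cols, index=X.index)[list(_COMPONENT_ORDER)]

    def luminal_low_posterior(self, prolif: np.ndarray) -> np.ndarray:
        """P(low-proliferation component | PROLIF score) for luminal cases."""
        check_is_fitted(self, "prolif_split_")
        sp = self.prolif_split_
        if self.luminal_split == "threshold":
            return (np.asarray(prolif, dtype=float) <= self.prolif_threshold).astype(float)
        from scipy.stats import norm

        lo = sp["pi_low"] * norm.pdf(prolif, sp["mu_low"], sp["sigma_low"])
        hi = (1 - sp["pi_low"]) * norm.pdf(prolif, sp["mu_high"], sp["sigma_high"])
        with np.errstate(invalid="ignore"):
            post = lo / (lo + hi)
        return np.where(np.isfinite(post), post, 0.5)

    def predict(self, X: pd.DataFrame):
        post = self.component_posterior(X)
        X = pd.DataFrame(X)
        if "PROLIF" not in X.columns:
            raise ValueError("score matrix lacks required module column 'PROLIF'")
        comp = np.argmax(post.to_numpy(), axis=1)  # first max -> canonical order
        prolif = X["PROLIF"].to_numpy(dtype=float)
        p_low = self.luminal_low_posterior(prolif)
        labels = []
        for i, c in enumerate(comp):
            name = _COMPONENT_ORDER[c]
            if name == "LUMINAL":
                labels.append(Subtype.LUMA if p_low[i] >= 0.5 else Subtype.LUMB)
            else:
                labels.append(Subtype(name))
        return np.array(labels, dtype=object)

    def predict_posterior(self, X: pd.DataFrame) -> pd.DataFrame:
        """Component posteriors plus the luminal-low posterior per sample."""
        post = self.component_posterior(X)
        X = pd.DataFrame(X)
        post = post.copy()
        post["P_LUMA_GIVEN_LUMINAL"] = self.luminal_low_posterior(
            X["PROLIF"].to_numpy(dtype=float)
        )
        return post


@dataclass(frozen=True)
class SCMModel:
    """Serializable fitted SCM (mixture parameters + component map + split)."""

    mgl_id: str
    weights: tuple
    means: tuple  # 3 x 2 over (ER, HER2)
    covariances: tuple  # 3 x 2 x 2
    comp_map: dict  # component index (as str in JSON) -> BASAL/HER2/LUMINAL
    prolif_split: dict
    luminal_split: str = "mixture"
    prolif_threshold: float = 0.0
    training_set_id: str = ""

    def to_classifier(self) -> SCMClassifier:
        clf = SCMClassifier(
            luminal_split=self.luminal_split, prolif_threshold=self.prolif_threshold
        )
        clf.gmm_ = _make_gmm_2d(self.weights, self.means, self.covariances)
        clf.comp_map_ = {int(k): v for k, v in self.comp_map.items()}
        clf.prolif_split_ = dict(self.prolif_split)
        clf.classes_ = np.array(
            [Subtype.BASAL, Subtype.HER2, Subtype.LUMA, Subtype.LUMB], dtype=object
        )
        return clf

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model_type": "SCM",
                    "mgl_id": self.mgl_id,
                    "training_set_id": self.training_set_id,
                    "weights": np.asarray(self.weights).tolist(),
                    "means": np.asarray(self.means).tolist(),
                    "covariances": np.asarray(self.covariances).tolist(),
                    "comp_map": {str(k): v for k, v in self.comp_map.items()},
                    "prolif_split": self.prolif_split,
                    "luminal_split": self.luminal_split,
                    "prolif_threshold": self.prolif_threshold,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SCMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mgl_id=d["mgl_id"],
            weights=tuple(d["weights"]),
            means=tuple(map(tuple, d["means"])),
            covariances=tuple(tuple(map(tuple, c)) for c in d["covariances"]),
            comp_map={int(k): v for k, v in d["comp_map"].items()},
            prolif_split=dict(d["prolif_split"]),
            luminal_split=d.get("luminal_split", "mixture"),
            prolif_threshold=float(d.get("prolif_threshold", 0.0)),
            training_set_id=d.get("training_set_id", ""),
        )

    @classmethod
    def from_classifier(
        cls, clf: SCMClassifier, mgl_id: str = "", training_set_id: str = ""
    ) -> "SCMModel":
        return cls(
            mgl_id=mgl_id,
            weights=tuple(clf.gmm_.weights_.tolist()),
            means=tuple(map(tuple, clf.gmm_.means_.tolist())),
            covariances=tuple(tuple(map(tuple, c)) for c in clf.gmm_.covariances_.tolist()),
            comp_map=dict(clf.comp_map_),
            prolif_split=dict(clf.prolif_split_),
            luminal_split=clf.luminal_split,
            prolif_threshold=clf.prolif_threshold,
            training_set_id=training_set_id,
        )


def fit_scm(
    scores: ModuleScoreMatrix,
    seed: int | None = None,
    n_restarts: int = 10,
    luminal_split: str = "mixture",
) -> SCMModel:
    """Fit an SCM on scaled module scores (unsupervised)."""
    if not scores.scaled:
        raise ValueError("SCM fitting requires scaled module scores")
    clf = SCMClassifier(
        n_restarts=n_restarts, random_state=seed, luminal_split=luminal_split
    ).fit(scores.scores)
    return SCMModel.from_classifier(
        clf, mgl_id=scores.mgl_id, training_set_id=scores.dataset_id
    )


def predict_scm(
    model: SCMModel,
    scores: ModuleScoreMatrix,
    predictor_id: str | None = None,
) -> tuple[SubtypeAssignment, pd.DataFrame]:
    """Posterior-based subtype assignment plus the posterior table."""
    if not scores.scaled:
        raise ValueError("SCM prediction requires scaled module scores")
    clf = model.to_classifier()
    labels = clf.predict(scores.scores)
    post = clf.predict_posterior(scores.scores)
    pid = predictor_id or f"SCM.{model.mgl_id}.{model.training_set_id}"
    assignment = SubtypeAssignment(
        sample_ids=tuple(scores.sample_ids), labels=tuple(labels), predictor_id=pid
    )
    return assignment, post
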