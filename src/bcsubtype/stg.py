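"""Rule-based subtype predictor from St. Gallen-style surrogate definitions.

Four markers — ER, HER2, PGR and proliferation — are dichotomized into
over(+)/under(-)expression on the scaled module-score axis, giving 2^4 = 16
status profiles. Each profile maps to one of the four intrinsic subtypes:

* HER2+ profiles map to HER2 (the original luminal B/HER2+ surrogate class
  is folded into HER2, which maximizes similarity with SCM assignments);
* HER2- profiles that are hormone-receptor positive (ER+ and/or PGR+) map
  to luminal A when proliferation is low and luminal B when high;
* HER2-, ER-, PGR- (triple-negative) profiles map to basal.

Cutpoints are estimated per marker as the equal-posterior point of a
univariate 2-component Gaussian mixture (between the component means); a
threshold mode with fixed cutpoints at 0 is available as fallback. A score
exactly at the cutpoint counts as underexpressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .core import Subtype, SubtypeAssignment
from .modules import ModuleScoreMatrix

__all__ = [
    "MARKERS",
    "STGClassifier",
    "STGModel",
    "default_rule_table",
    "equal_posterior_cutpoint",
    "fit_stg",
    "predict_stg",
]

#: marker order used for profile strings, e.g. "+-+-" = ER+, HER2-, PGR+, PROLIF-
MARKERS: tuple[str, ...] = ("ER", "HER2", "PGR", "PROLIF")


def default_rule_table() -> dict[str, Subtype]:
    """The 16-entry profile -> subtype table (4-subtype taxonomy)."""
    table: dict[str, Subtype] = {}
    for er in "+-":
        for her2 in "+-":
            for pgr in "+-":
                for prolif in "+-":
                    profile = er + her2 + pgr + prolif
                    if her2 == "+":
                        sub = Subtype.HER2
                    elif er == "+" or pgr == "+":
                        sub = Subtype.LUMA if prolif == "-" else Subtype.LUMB
                    else:
                        sub = Subtype.BASAL
                    table[profile] = sub
    return table


def equal_posterior_cutpoint(
    pi1: float, mu1: float, sigma1: float, pi2: float, mu2: float, sigma2: float
) -> float:
    """Point between two Gaussian component means with equal posteriors.

    Solves ``pi1 N(x; mu1, sigma1) = pi2 N(x; mu2, sigma2)`` for x, searching
    first between the means and then on a widened bracket. Component 1 is
    taken as the lower-mean component.
    """
    if mu1 > mu2:
        pi1, mu1, sigma1, pi2, mu2, sigma2 = pi2, mu2, sigma2, pi1, mu1, sigma1

    def f(x: float) -> float:
        return (np.log(pi1) + norm.logpdf(x, mu1, sigma1)) - (
            np.log(pi2) + norm.logpdf(x, mu2, sigma2)
        )

    lo, hi = mu1, mu2
    if f(lo) * f(hi) > 0:
        lo, hi = mu1 - 6 * sigma1, mu2 + 6 * sigma2
        xs = np.linspace(lo, hi, 512)
        fs = np.array([f(x) for x in xs])
        sign_change = np.where(np.diff(np.sign(fs)) != 0)[0]
        if len(sign_change) == 0:
            raise ValueError("no equal-posterior point found between the components")
        # pick the sign change closest to the midpoint of the means
        mid = 0.5 * (mu1 + mu2)
        i = sign_change[np.argmin(np.abs(xs[sign_change] - mid))]
        lo, hi = xs[i], xs[i + 1]
    return float(brentq(f, lo, hi, xtol=1e-12))


class STGClassifier(BaseEstimator, ClassifierMixin):
    """Dichotomize four marker scores and look the profile up in a rule table.

    Parameters
    ----------
    cutpoint_method : "mixture" (equal-posterior point of a per-marker
        2-component Gaussian mixture) or "threshold" (all cutpoints at
        ``threshold``).
    threshold : fixed cutpoint used in threshold mode.
    separation_floor : minimum |mu_high - mu_low| for a mixture-based
        cutpoint; below it the fit is reported degenerate.
    on_degenerate : "error" raises on a degenerate marker mixture (no
        equal-posterior crossing, or separation below the floor);
        "threshold" falls back to the fixed cutpoint for that marker and
        records it in ``degenerate_markers_``.
    """

    def __init__(
        self,
        cutpoint_method: str = "mixture",
        threshold: float = 0.0,
        separation_floor: float = 0.1,
        n_restarts: int = 5,
        min_samples: int = 30,
        on_degenerate: str = "error",
        random_state: int | None = None,
    ):
        self.cutpoint_method = cutpoint_method
        self.threshold = threshold
        self.separation_floor = separation_floor
        self.n_restarts = n_restarts
        self.min_samples = min_samples
        self.on_degenerate = on_degenerate
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        missing = [mk for mk in MARKERS if mk not in X.columns]
        if missing:
            raise ValueError(f"score matrix lacks marker columns {missing}")
        if len(X) < self.min_samples:
            raise ValueError(
                f"STG fitting requires >= {self.min_samples} samples, got {len(X)}"
            )
        cutpoints: dict[str, float] = {}
        degenerate: list[str] = []
        if self.cutpoint_method == "threshold":
            cutpoints = {mk: float(self.threshold) for mk in MARKERS}
        else:
            for mk in MARKERS:
                v = X[mk].to_numpy(dtype=float).reshape(-1, 1)
                gm = GaussianMixture(
                    n_components=2,
                    n_init=self.n_restarts,
                    init_params="k-means++",
                    random_state=self.random_state,
                    reg_covar=1e-8,
                ).fit(v)
                mus = gm.means_.ravel()
                sds = np.sqrt(gm.covariances_.reshape(2))
                try:
                    if abs(mus[1] - mus[0]) < self.separation_floor:
                        raise ValueError(
                            f"marker {mk}: component means {mus[0]:.3f} and "
                            f"{mus[1]:.3f} are closer than the separation floor "
                            f"{self.separation_floor}; consider cutpoint_method="
                            "'threshold'"
                        )
                    cutpoints[mk] = equal_posterior_cutpoint(
                        gm.weights_[0], mus[0], sds[0], gm.weights_[1], mus[1], sds[1]
                    )
                except ValueError:
                    if self.on_degenerate != "threshold":
                        raise
                    cutpoints[mk] = float(self.threshold)
                    degenerate.append(mk)
        self.cutpoints_ = cutpoints
        self.degenerate_markers_ = degenerate
        self.rule_table_ = default_rule_table()
        self.classes_ = np.array(
            [Subtype.BASAL, Subtype.HER2, Subtype.LUMA, Subtype.LUMB], dtype=object
        )
        return self

    def profiles(self, X: pd.DataFrame) -> pd.Series:
        """Status profile string per sample; '+' iff score > cutpoint."""
        check_is_fitted(self, "cutpoints_")
        X = pd.DataFrame(X)
        missing = [mk for mk in MARKERS if mk not in X.columns]
        if missing:
            raise ValueError(f"score matrix lacks marker columns {missing}")
        status = [
            np.where(X[mk].to_numpy(dtype=float) > self.cutpoints_[mk], "+", "-")
            for mk in MARKERS
        ]
        out = ["".join(row) for row in zip(*status)]
        return pd.Series(out, index=X.index)

    def predict(self, X: pd.DataFrame):
        prof = self.profiles(X)
        return np.array([self.rule_table_[p] for p in prof], dtype=object)


@dataclass(frozen=True)
class STGModel:
    """Serializable fitted STG: per-marker cutpoints plus the rule table."""

    mgl_id: str
    cutpoints: dict  # marker -> float
    rule_table: dict  # profile string -> subtype value
    training_set_id: str = ""

    def __post_init__(self) -> None:
        profiles = {
            er + her2 + pgr + prolif
            for er in "+-" for her2 in "+-" for pgr in "+-" for prolif in "+-"
        }
        if set(self.rule_table) != profiles:
            missing = sorted(profiles - set(self.rule_table))
            extra = sorted(set(self.rule_table) - profiles)
            raise ValueError(
                f"rule table must be total over 16 profiles; missing {missing}, "
                f"unexpected {extra}"
            )
        if set(self.cutpoints) != set(MARKERS):
            raise ValueError(f"cutpoints must cover markers {MARKERS}")

    def to_classifier(self) -> STGClassifier:
        clf = STGClassifier()
        clf.cutpoints_ = {k: float(v) for k, v in self.cutpoints.items()}
        clf.rule_table_ = {k: Subtype(v) for k, v in self.rule_table.items()}
        clf.classes_ = np.array(
            [Subtype.BASAL, Subtype.HER2, Subtype.LUMA, Subtype.LUMB], dtype=object
        )
        return clf

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model_type": "STG",
                    "mgl_id": self.mgl_id,
                    "training_set_id": self.training_set_id,
                    "cutpoints": {k: float(v) for k, v in self.cutpoints.items()},
                    "rule_table": {
                        k: (v.value if isinstance(v, Subtype) else str(v))
                        for k, v in self.rule_table.items()
                    },
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "STGModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mgl_id=d["mgl_id"],
            cutpoints=dict(d["cutpoints"]),
            rule_table=dict(d["rule_table"]),
            training_set_id=d.get("training_set_id", ""),
        )


def fit_stg(
    scores: ModuleScoreMatrix,
    seed: int | None = None,
    cutpoint_method: str = "mixture",
    on_degenerate: str = "error",
) -> STGModel:
    """Estimate per-marker cutpoints on scaled scores; fixed rule table."""
    if not scores.scaled:
        raise ValueError("STG fitting requires scaled module scores")
    clf = STGClassifier(
        cutpoint_method=cutpoint_method, on_degenerate=on_degenerate, random_state=seed
    ).fit(scores.scores)
    return STGModel(
        mgl_id=scores.mgl_id,
        cutpoints=dict(clf.cutpoints_),
        rule_table={k: v.value for k, v in clf.rule_table_.items()},
        training_set_id=scores.dataset_id,
    )


def predict_stg(
    model: STGModel,
    scores: ModuleScoreMatrix,
    predictor_id: str | None = None,
) -> tuple[SubtypeAssignment, pd.Series]:
    """Profile-based assignment plus the status profile per sample."""
    if not scores.scaled:
        raise ValueError("STG prediction requires scaled module scores")
    clf = model.to_classifier()
    prof = clf.profiles(scores.scores)
    labels = np.array([clf.rule_table_[p] for p in prof], dtype=object)
    pid = predictor_id or f"STG.{model.mgl_id}.{model.training_set_id}"
    assignment = SubtypeAssignment(
        sample_ids=tuple(scores.sample_ids), labels=tuple(labels), predictor_id=pid
    )
    return assignment, prof
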