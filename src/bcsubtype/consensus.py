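"""Consensus-set construction and consensus-trained predictor suites.

For a training cohort T, a panel of predictors assigns a subtype to every
sample; the consensus set (CS) of T is the subset of samples on which all
panel members agree, together with the agreed labels. The default panel
mirrors the five-predictor scheme: a user-supplied reference nearest-
centroid model (the "classic" SSP role) applied to robustly scaled T, three
SCMs fitted on T's scaled module scores (one per MGL), and one STG fitted
on T (first MGL's modules plus the single-gene PGR module).

A CS then serves as a supervised training cohort: three SSPs (one per IGL),
three SCMs and three STGs are trained on the CS samples only, giving the
nine consensus-trained models whose mutual concordance the package
evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import (
    SUBTYPE_ORDER,
    ExpressionMatrix,
    GeneListSet,
    Subtype,
    SubtypeAssignment,
)
from .modules import score_matrix
from .preprocess import robust_scale
from .scm import SCMModel, fit_scm, predict_scm
from .ssp import SSPModel, predict_ssp, train_ssp
from .stg import STGModel, fit_stg, predict_stg

__all__ = [
    "ConsensusSet",
    "build_consensus",
    "default_panel",
    "train_cs_suite",
    "apply_model",
]


@dataclass(frozen=True)
class ConsensusSet:
    """Samples concordantly subtyped by every panel predictor."""

    source_dataset_id: str
    sample_ids: tuple[str, ...]
    labels: tuple[Subtype, ...]
    retained_fraction: float
    per_subtype_counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_assignment(self, predictor_id: str = "consensus") -> SubtypeAssignment:
        return SubtypeAssignment(
            sample_ids=self.sample_ids, labels=self.labels, predictor_id=predictor_id
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# source_dataset: {self.source_dataset_id}\n")
            fh.write(f"# retained_fraction: {self.retained_fraction:.4f}\n")
            for s in SUBTYPE_ORDER:
                fh.write(f"# n_{s.value}: {self.per_subtype_counts.get(s.value, 0)}\n")
            fh.write("sample_id\tsubtype\n")
            for sid, lab in zip(self.sample_ids, self.labels):
                fh.write(f"{sid}\t{lab.value}\n")

    def summary(self) -> pd.DataFrame:
        """One-row summary in the layout of a consensus-set statistics table."""
        row = {
            "dataset": self.source_dataset_id,
            "n_cs": len(self),
            "retained_fraction": self.retained_fraction,
        }
        for s in SUBTYPE_ORDER:
            row[s.value] = self.per_subtype_counts.get(s.value, 0)
        return pd.DataFrame([row])


def build_consensus(
    assignments: list[SubtypeAssignment],
    source_dataset_id: str = "",
) -> ConsensusSet:
    """Retain exactly the samples on which all assignments agree."""
    if len(assignments) < 2:
        raise ValueError("need at least 2 assignment sets to build a consensus")
    universe = assignments[0].sample_ids
    uni_set = set(universe)
    for a in assignments[1:]:
        if set(a.sample_ids) != uni_set:
            diff = sorted(uni_set ^ set(a.sample_ids))
            raise ValueError(
                f"sample universes differ (predictor {a.predictor_id!r}); "
                f"symmetric difference: {diff[:10]}"
            )
    aligned = [a.reindex(universe) for a in assignments]
    kept_ids: list[str] = []
    kept_labels: list[Subtype] = []
    for i, sid in enumerate(universe):
        labels = {a.labels[i] for a in aligned}
        if len(labels) == 1:
            kept_ids.append(sid)
            kept_labels.append(aligned[0].labels[i])
    counts = {s.value: 0 for s in SUBTYPE_ORDER}
    for l in kept_labels:
        counts[l.value] += 1
    return ConsensusSet(
        source_dataset_id=source_dataset_id,
        sample_ids=tuple(kept_ids),
        labels=tuple(kept_labels),
        retained_fraction=len(kept_ids) / len(universe) if universe else 0.0,
        per_subtype_counts=counts,
    )


def default_panel(
    T: ExpressionMatrix,
    reference_ssp: SSPModel,
    mgls: list[GeneListSet],
    seed: int,
    pgr_gene: str | None = None,
    coverage_floor: float = 0.5,
    stg_mgl_index: int = 0,
) -> list[SubtypeAssignment]:
    """The five-predictor consensus panel applied to a training cohort.

    Returns assignments from (i) the reference SSP on robustly scaled T,
    (ii) three SCMs fitted on T's scaled module scores, (iii) one STG
    fitted on T using ``mgls[stg_mgl_index]``'s modules plus the
    single-gene PGR module.
    """
    if len(mgls) != 3:
        raise ValueError(f"the default panel uses exactly 3 MGLs, got {len(mgls)}")
    scaled = robust_scale(T)
    out = [predict_ssp(reference_ssp, scaled, predictor_id="panel.SSP.ref")]
    score_cache = {}
    for i, mgl in enumerate(mgls):
        scores = score_matrix(
            T, mgl, scale=True, coverage_floor=coverage_floor, pgr_gene=pgr_gene
        )
        score_cache[i] = scores
        model = fit_scm(scores, seed=seed + i)
        a, _ = predict_scm(model, scores, predictor_id=f"panel.SCM.{mgl.list_id}")
        out.append(a)
    stg_scores = score_cache[stg_mgl_index]
    if "PGR" not in stg_scores.module_ids:
        raise ValueError(
            "STG panel member needs a PGR score; pass pgr_gene for MGLs "
            "without a PGR module"
        )
    stg_model = fit_stg(stg_scores, seed=seed + 100, on_degenerate="threshold")
    a, _ = predict_stg(
        stg_model, stg_scores, predictor_id=f"panel.STG.{mgls[stg_mgl_index].list_id}"
    )
    out.append(a)
    return out


def train_cs_suite(
    cs: ConsensusSet,
    T: ExpressionMatrix,
    igls: list[GeneListSet],
    mgls: list[GeneListSet],
    seed: int,
    pgr_gene: str | None = None,
    min_class_size: int = 5,
    metric: str = "spearman",
) -> dict[tuple[str, str], object]:
    """Train the nine consensus-based models (3 SSPs, 3 SCMs, 3 STGs).

    Expression is robustly scaled (and module scores computed and scaled)
    within the full cohort T, then restricted to the CS samples for
    training. Keys of the returned dict are (predictor_type, gene_list_id);
    every model's ``training_set_id`` is the consensus set's source dataset.
    """
    for s in SUBTYPE_ORDER:
        if cs.per_subtype_counts.get(s.value, 0) < min_class_size:
            raise ValueError(
                f"consensus set {cs.source_dataset_id!r} has "
                f"{cs.per_subtype_counts.get(s.value, 0)} {s.value} samples, "
                f"fewer than min_class_size={min_class_size}"
            )
    models: dict[tuple[str, str], object] = {}
    scaled_cs = robust_scale(T).subset_samples(list(cs.sample_ids))
    labels = cs.to_assignment()
    for igl in igls:
        models[("SSP", igl.list_id)] = train_ssp(
            scaled_cs, labels, igl, metric=metric, min_class_size=min_class_size
        )
    for i, mgl in enumerate(mgls):
        scores = score_matrix(T, mgl, scale=True, pgr_gene=pgr_gene)
        cs_scores = scores.subset_samples(list(cs.sample_ids))
        cs_scores.dataset_id = cs.source_dataset_id
        models[("SCM", mgl.list_id)] = fit_scm(cs_scores, seed=seed + i)
        models[("STG", mgl.list_id)] = fit_stg(
            cs_scores, seed=seed + 50 + i, on_degenerate="threshold"
        )
    for model in models.values():
        object.__setattr__(model, "training_set_id", cs.source_dataset_id)
    return models


def apply_model(
    model: object,
    V: ExpressionMatrix,
    mgls: dict[str, GeneListSet] | None = None,
    pgr_gene: str | None = None,
    predictor_id: str | None = None,
) -> SubtypeAssignment:
    """Apply any fitted subtype model to an unscaled gene-level cohort.

    Handles the per-dataset preprocessing each predictor type expects:
    robust scaling of expression for an SSP, scaled module scores (looked
    up by the model's ``mgl_id`` in ``mgls``) for SCM and STG.
    """
    if isinstance(model, SSPModel):
        return predict_ssp(model, robust_scale(V), predictor_id=predictor_id)
    if isinstance(model, (SCMModel, STGModel)):
        if mgls is None or model.mgl_id not in mgls:
            raise ValueError(
                f"module-score models need the MGL {model.mgl_id!r} to score "
                "the validation cohort"
            )
        scores = score_matrix(V, mgls[model.mgl_id], scale=True, pgr_gene=pgr_gene)
        if isinstance(model, SCMModel):
            return predict_scm(model, scores, predictor_id=predictor_id)[0]
        return predict_stg(model, scores, predictor_id=predictor_id)[0]
    raise TypeError(f"unsupported model type {type(model).__name__}")
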