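"""Per-sample module scores for the ER, HER2, proliferation and PGR phenotypes.

A module score summarizes one biological phenotype as the signed weighted
average of a sample's (unscaled, log2, gene-level) expression over the
module's genes:

    score(s) = sum_i w_i * x_is / sum_i |w_i|

Genes absent from the data are dropped and the denominator renormalized,
provided at least a configurable fraction (coverage floor, default 0.5) of
the module's genes is present. Scores are computed on unscaled expression
and, when requested, subsequently robustly scaled per module column within
the dataset — the score columns are treated exactly like a small feature
matrix by the percentile scaler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneListSet
from .preprocess import RobustPercentileScaler

__all__ = ["ModuleScoreMatrix", "compute_module_score", "score_matrix"]


@dataclass
class ModuleScoreMatrix:
    """Samples x modules score matrix with per-module gene coverage."""

    scores: pd.DataFrame  # samples x modules
    mgl_id: str = ""
    scaled: bool = False
    dataset_id: str = ""
    coverage: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def module_ids(self) -> list[str]:
        return list(self.scores.columns)

    def subset_samples(self, sample_ids) -> "ModuleScoreMatrix":
        return ModuleScoreMatrix(
            scores=self.scores.loc[list(sample_ids)],
            mgl_id=self.mgl_id,
            scaled=self.scaled,
            dataset_id=self.dataset_id,
            coverage=dict(self.coverage),
        )

    def write_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path, mgl_id: str = "", scaled: bool = False) -> "ModuleScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(scores=df, mgl_id=mgl_id, scaled=scaled)


def compute_module_score(
    m: ExpressionMatrix,
    module: list[tuple[str, float]],
    coverage_floor: float = 0.5,
) -> pd.Series:
    """Signed weighted average of expression over one module's genes.

    Duplicate (gene, weight) entries are merged before averaging, so the
    score is invariant to gene ordering and entry duplication.
    """
    merged: dict[str, float] = {}
    for g, w in module:
        merged[str(g)] = float(w)
    genes = list(merged)
    present = [g for g in genes if g in set(m.feature_ids)]
    coverage = len(present) / len(genes) if genes else 0.0
    if coverage < coverage_floor:
        raise ValueError(
            f"module coverage {coverage:.2f} below floor {coverage_floor:.2f} "
            f"({len(present)}/{len(genes)} genes present)"
        )
    df = m.to_frame()
    w = np.array([merged[g] for g in present])
    x = df.loc[present].to_numpy()
    score = (w @ x) / np.abs(w).sum()
    return pd.Series(score, index=m.sample_ids)


def score_matrix(
    m: ExpressionMatrix,
    mgl: GeneListSet,
    scale: bool = True,
    coverage_floor: float = 0.5,
    pgr_gene: str | None = None,
) -> ModuleScoreMatrix:
    """Compute (and optionally robustly scale) all module scores of an MGL.

    Parameters
    ----------
    m : gene-level, unscaled expression matrix.
    mgl : module gene list; must contain at least ER, HER2 and PROLIF.
    scale : robustly scale each score column within this dataset.
    pgr_gene : single-gene PGR module used when the MGL has no PGR module
        (the PGR phenotype is always measured by the same single-gene
        module across MGLs).
    """
    if mgl.kind != "MGL":
        raise ValueError(f"gene list {mgl.list_id!r} is not an MGL")
    if m.level != "gene":
        raise ValueError("module scores require a gene-level matrix")
    if m.scaled:
        raise ValueError("module scores must be computed on unscaled expression")
    modules = dict(mgl.modules)
    if "PGR" not in modules and pgr_gene is not None:
        modules["PGR"] = ((str(pgr_gene), 1.0),)
    cols: dict[str, pd.Series] = {}
    coverage: dict[str, float] = {}
    for mid, entries in modules.items():
        merged = {str(g): float(w) for g, w in entries}
        present = [g for g in merged if g in set(m.feature_ids)]
        coverage[mid] = len(present) / len(merged) if merged else 0.0
        cols[mid] = compute_module_score(m, list(entries), coverage_floor)
    scores = pd.DataFrame(cols)
    if scale:
        scaler = RobustPercentileScaler().fit(scores)
        scores = scaler.transform(scores)
    return ModuleScoreMatrix(
        scores=scores,
        mgl_id=mgl.list_id,
        scaled=scale,
        dataset_id=m.dataset_id,
        coverage=coverage,
    )
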