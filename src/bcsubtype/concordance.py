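"""Concordance analysis between subtype assignments.

Agreement between two predictors on the same samples is measured by the
percentage of concordant samples (cc) and Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where p_o is the observed agreement (trace of the contingency table over n)
and p_e the agreement expected by chance from the row/column marginals.
Kappa values are reported with the usual qualitative bands: 0-0.2 slight,
0.21-0.4 fair, 0.41-0.6 moderate, 0.61-0.8 substantial, 0.81-1 almost
perfect (negative values fall in "slight").

Subtype-specific kappa binarizes both assignment vectors to "s vs not s"
before tabulating. The degenerate case p_e = 1 (both raters constant and
equal, e.g. a subtype absent from both vectors after binarization) leaves
kappa undefined; it is returned flagged rather than coerced to 0 or 1, and
aggregation excludes flagged results with a count.

``aggregate_concordance`` implements the comparison-partitioning protocol:
predictor pairs are grouped by whether the gene list, the consensus
training set, or both differ (or the predictor types differ), pairs whose
validation set coincides with either training set are excluded, and median
/ min / max of kappa and cc are reported per group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SUBTYPE_ORDER, Subtype, SubtypeAssignment

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "ComparisonGroup",
    "ComparisonDesign",
    "kappa_band",
    "cohens_kappa",
    "subtype_kappa",
    "aggregate_concordance",
]

BANDS = ("slight", "fair", "moderate", "substantial", "almost_perfect")


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value.

    Interval endpoints follow the printed convention: kappa of exactly 0.2,
    0.4, 0.6 and 0.8 fall in the lower band; negative values are "slight".
    """
    if kappa <= 0.2:
        return "slight"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "substantial"
    return "almost_perfect"


@dataclass(frozen=True)
class ContingencyTable:
    """Square label x label count table in canonical label order."""

    labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, a, b, label_order=None) -> "ContingencyTable":
        a = [str(getattr(x, "value", x)) for x in a]
        b = [str(getattr(x, "value", x)) for x in b]
        if label_order is None:
            observed = set(a) | set(b)
            canon = [s.value for s in SUBTYPE_ORDER if s.value in observed]
            extra = sorted(observed - set(canon))
            label_order = tuple(canon + extra)
        idx = {l: i for i, l in enumerate(label_order)}
        counts = np.zeros((len(label_order), len(label_order)), dtype=int)
        for x, y in zip(a, b):
            counts[idx[x], idx[y]] += 1
        return cls(labels=tuple(label_order), counts=counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class KappaResult:
    """Overall kappa, percentage concordance, per-subtype kappas and band."""

    kappa: float
    cc: float
    n: int
    band: str | None
    table: ContingencyTable
    per_subtype_kappa: dict = field(default_factory=dict)
    degenerate: bool = False


def _kappa_from_table(table: ContingencyTable) -> tuple[float, float, bool]:
    """Return (kappa, cc, degenerate) from a contingency table."""
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    counts = table.counts
    p_o = np.trace(counts) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    p_e = float(row @ col)
    cc = 100.0 * p_o
    if p_e >= 1.0 - 1e-15:
        return float("nan"), cc, True
    return (p_o - p_e) / (1.0 - p_e), cc, False


def _check_universe(a: SubtypeAssignment, b: SubtypeAssignment) -> SubtypeAssignment:
    if set(a.sample_ids) != set(b.sample_ids):
        diff = sorted(set(a.sample_ids) ^ set(b.sample_ids))
        raise ValueError(f"sample universes differ; symmetric difference: {diff[:10]}")
    return b.reindex(a.sample_ids)


def cohens_kappa(a: SubtypeAssignment, b: SubtypeAssignment) -> KappaResult:
    """Cohen's kappa, cc and per-subtype kappas for two assignments."""
    if len(a) == 0:
        raise ValueError("need at least one sample")
    b = _check_universe(a, b)
    table = ContingencyTable.from_labels(a.labels, b.labels)
    kappa, cc, degenerate = _kappa_from_table(table)
    per_subtype = {}
    for s in table.labels:
        try:
            sub = Subtype(s)
        except ValueError:
            continue
        per_subtype[s] = subtype_kappa(a, b, sub).kappa
    return KappaResult(
        kappa=kappa,
        cc=cc,
        n=table.n,
        band=None if degenerate else kappa_band(kappa),
        table=table,
        per_subtype_kappa=per_subtype,
        degenerate=degenerate,
    )


def subtype_kappa(a: SubtypeAssignment, b: SubtypeAssignment, s: Subtype) -> KappaResult:
    """Kappa of the one-vs-rest binarized assignments for subtype ``s``."""
    if len(a) == 0:
        raise ValueError("need at least one sample")
    b = _check_universe(a, b)
    s = Subtype(s)
    bin_a = [s.value if l == s else f"not_{s.value}" for l in a.labels]
    bin_b = [s.value if l == s else f"not_{s.value}" for l in b.labels]
    table = ContingencyTable.from_labels(
        bin_a, bin_b, label_order=(s.value, f"not_{s.value}")
    )
    kappa, cc, degenerate = _kappa_from_table(table)
    return KappaResult(
        kappa=kappa,
        cc=cc,
        n=table.n,
        band=None if degenerate else kappa_band(kappa),
        table=table,
        degenerate=degenerate,
    )


class ComparisonGroup(str, enum.Enum):
    BOTH_DIFFER = "both_differ"
    GENE_LIST_DIFFERS = "gene_list_differs"
    CS_DIFFERS = "cs_differs"
    INTER_TYPE = "inter_type"
    IDENTICAL = "identical"


@dataclass(frozen=True)
class ComparisonDesign:
    """Metadata of one predictor-pair comparison on one validation set."""

    type_a: str
    type_b: str
    gene_list_a: str
    gene_list_b: str
    cs_a: str
    cs_b: str
    validation_dataset: str

    @property
    def group(self) -> ComparisonGroup:
        if self.type_a != self.type_b:
            return ComparisonGroup.INTER_TYPE
        gl_diff = self.gene_list_a != self.gene_list_b
        cs_diff = self.cs_a != self.cs_b
        if gl_diff and cs_diff:
            return ComparisonGroup.BOTH_DIFFER
        if gl_diff:
            return ComparisonGroup.GENE_LIST_DIFFERS
        if cs_diff:
            return ComparisonGroup.CS_DIFFERS
        return ComparisonGroup.IDENTICAL

    @property
    def train_validation_overlap(self) -> bool:
        return self.validation_dataset in (self.cs_a, self.cs_b)


def _summary(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": int(arr.size),
    }


def aggregate_concordance(
    results: list[tuple[ComparisonDesign, KappaResult]],
) -> dict:
    """Per-group summaries of kappa/cc over included comparison results.

    Comparisons whose validation set equals either training (consensus) set
    are excluded, as are degenerate kappa results; both exclusions are
    counted in the output.
    """
    if not results:
        raise ValueError("no comparison results to aggregate")
    n_overlap = sum(1 for d, _ in results if d.train_validation_overlap)
    n_degenerate = sum(
        1 for d, r in results if not d.train_validation_overlap and r.degenerate
    )
    included = [
        (d, r)
        for d, r in results
        if not d.train_validation_overlap and not r.degenerate
    ]
    if not included:
        raise ValueError(
            f"all {len(results)} results excluded "
            f"({n_overlap} train/validation overlap, {n_degenerate} degenerate)"
        )
    out: dict = {
        "n_excluded_overlap": n_overlap,
        "n_excluded_degenerate": n_degenerate,
        "groups": {},
    }
    by_group: dict[str, list[tuple[ComparisonDesign, KappaResult]]] = {}
    for d, r in included:
        by_group.setdefault(d.group.value, []).append((d, r))
    for gname, items in by_group.items():
        kappas = [r.kappa for _, r in items]
        ccs = [r.cc for _, r in items]
        per_subtype: dict[str, list[float]] = {}
        for _, r in items:
            for s, k in r.per_subtype_kappa.items():
                if np.isfinite(k):
                    per_subtype.setdefault(s, []).append(k)
        out["groups"][gname] = {
            "kappa": _summary(kappas),
            "cc": _summary(ccs),
            "per_subtype_kappa": {s: _summary(v) for s, v in per_subtype.items()},
        }
    return out
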