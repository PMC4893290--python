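"""Shared domain types for molecular subtyping of breast cancer expression data.

The package works with log2-scale expression matrices (features x samples),
probeset-to-gene mappings, intrinsic gene lists (IGLs) and module gene lists
(MGLs), and per-sample subtype assignments over the four intrinsic subtypes
on which broad agreement exists: basal, HER2, luminal A and luminal B.

All tabular artefacts are read and written as plain tab-delimited text so
that every stage of the pipeline can be inspected and diffed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subtype",
    "SUBTYPE_ORDER",
    "ExpressionMatrix",
    "GeneMapping",
    "SubtypeAssignment",
    "GeneListSet",
    "MODULE_IDS",
    "validate_matrix",
    "read_gene_lists",
    "write_gene_lists",
    "read_assignments",
    "write_assignments",
]


class Subtype(str, enum.Enum):
    """The four intrinsic breast cancer subtypes handled by this package.

    The normal-like subtype is deliberately not part of the vocabulary; a
    loaded five-centroid reference model is reduced to these four classes.
    The enum order is the canonical order used for every tie-break and
    table layout in the package.
    """

    BASAL = "BASAL"
    HER2 = "HER2"
    LUMA = "LUMA"
    LUMB = "LUMB"

    def __lt__(self, other: "Subtype") -> bool:  # total canonical order
        return SUBTYPE_ORDER.index(self) < SUBTYPE_ORDER.index(other)


SUBTYPE_ORDER: tuple[Subtype, ...] = (
    Subtype.BASAL,
    Subtype.HER2,
    Subtype.LUMA,
    Subtype.LUMB,
)

#: module identifiers used for module scores (ER signalling, HER2 signalling,
#: proliferation, progesterone receptor)
MODULE_IDS: tuple[str, ...] = ("ER", "HER2", "PROLIF", "PGR")


def _has_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2 expression values.

    Parameters
    ----------
    feature_ids : ordered probeset or gene identifiers (rows).
    sample_ids : ordered sample identifiers (columns).
    values : 2-D array, shape ``(len(feature_ids), len(sample_ids))``.
    dataset_id : label of the dataset (cohort) the samples belong to.
    level : ``"probeset"`` or ``"gene"``.
    scaled : whether robust percentile scaling has been applied.
    meta : free-form provenance (e.g. chosen probeset per gene after
        collapsing, replicate-pair structure of simulated data).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dataset_id: str = ""
    level: str = "gene"
    scaled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)

    # -- container conveniences -------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return the matrix as a DataFrame (features x samples)."""
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        dataset_id: str = "",
        level: str = "gene",
        scaled: bool = False,
        meta: dict | None = None,
    ) -> "ExpressionMatrix":
        return cls(
            feature_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            dataset_id=dataset_id,
            level=level,
            scaled=scaled,
            meta=dict(meta or {}),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in cols],
            values=self.values[:, cols],
            dataset_id=self.dataset_id,
            level=self.level,
            scaled=self.scaled,
            meta=dict(self.meta),
        )

    # -- IO ----------------------------------------------------------------
    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(
        cls, path, dataset_id: str = "", level: str = "gene", scaled: bool = False
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, dataset_id=dataset_id, level=level, scaled=scaled)


def validate_matrix(m: ExpressionMatrix) -> list[str]:
    """Check the :class:`ExpressionMatrix` invariants; never raises.

    Returns an empty list iff the matrix is well formed; otherwise a list of
    human-readable violation descriptions naming the offending identifiers.
    """
    violations: list[str] = []
    for dup in _has_duplicates(m.feature_ids):
        violations.append(f"duplicate feature_id: {dup}")
    for dup in _has_duplicates(m.sample_ids):
        violations.append(f"duplicate sample_id: {dup}")
    shape = np.shape(m.values)
    expected = (len(m.feature_ids), len(m.sample_ids))
    if shape != expected:
        violations.append(
            f"dimension mismatch: values shape {shape} != "
            f"(|feature_ids|, |sample_ids|) = {expected}"
        )
    else:
        bad = ~np.isfinite(m.values)
        # NaN marks an explicitly-missing value at probeset level; +-inf never valid
        if np.isinf(m.values).any():
            rows = [m.feature_ids[i] for i in np.unique(np.where(np.isinf(m.values))[0])]
            violations.append(f"non-finite (infinite) values in features: {rows[:5]}")
        if m.level == "gene" and bad.any():
            rows = [m.feature_ids[i] for i in np.unique(np.where(bad)[0])]
            violations.append(
                f"missing values not allowed at gene level; features: {rows[:5]}"
            )
    return violations


@dataclass(frozen=True)
class GeneMapping:
    """Many-to-one probeset -> gene mapping (each probeset maps once)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", {str(k): str(v) for k, v in dict(self.entries).items()}
        )

    def gene_of(self, feature_id: str) -> str | None:
        return self.entries.get(feature_id)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"feature_id": list(self.entries), "gene_id": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneMapping":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df["feature_id"].duplicated().any():
            dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicate feature_id in mapping: {dups}")
        return cls(entries=dict(zip(df["feature_id"], df["gene_id"])))


@dataclass(frozen=True)
class SubtypeAssignment:
    """Per-sample subtype labels produced by one predictor."""

    sample_ids: tuple[str, ...]
    labels: tuple[Subtype, ...]
    predictor_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(
            self, "labels", tuple(Subtype(l) for l in self.labels)
        )
        if len(self.sample_ids) != len(self.labels):
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(
            [l.value for l in self.labels], index=list(self.sample_ids), name=self.predictor_id
        )

    def label_of(self, sample_id: str) -> Subtype:
        return self.labels[self.sample_ids.index(sample_id)]

    def reindex(self, sample_ids: Sequence[str]) -> "SubtypeAssignment":
        """Reorder to the given sample universe (must be a permutation)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing or len(sample_ids) != len(self.sample_ids):
            raise ValueError(f"sample universe mismatch; missing {missing[:5]}")
        return SubtypeAssignment(
            sample_ids=tuple(sample_ids),
            labels=tuple(self.labels[pos[s]] for s in sample_ids),
            predictor_id=self.predictor_id,
        )


def write_assignments(assignments: Iterable[SubtypeAssignment], path) -> None:
    rows = []
    for a in assignments:
        for s, l in zip(a.sample_ids, a.labels):
            rows.append((s, a.predictor_id, l.value))
    pd.DataFrame(rows, columns=["sample_id", "predictor_id", "subtype"]).to_csv(
        path, sep="\t", index=False
    )


def read_assignments(path) -> list[SubtypeAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for pid, grp in df.groupby("predictor_id", sort=False):
        out.append(
            SubtypeAssignment(
                sample_ids=tuple(grp["sample_id"]),
                labels=tuple(Subtype(s) for s in grp["subtype"]),
                predictor_id=str(pid),
            )
        )
    return out


@dataclass(frozen=True)
class GeneListSet:
    """An intrinsic gene list (IGL) or module gene list (MGL).

    An IGL is a flat list of gene identifiers defining the feature space of
    a nearest-centroid predictor. An MGL maps module identifiers (ER, HER2,
    PROLIF and optionally PGR) to signed-weight gene lists; when PGR is
    absent it is supplied externally as a single-gene module.

    Gene identifiers are opaque strings; Entrez semantics are a convention,
    not enforced, so synthetic universes work throughout.
    """

    list_id: str
    kind: str  # "IGL" | "MGL"
    genes: tuple[str, ...] = ()
    modules: Mapping[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("IGL", "MGL"):
            raise ValueError(f"kind must be IGL or MGL, got {self.kind!r}")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        mods = {
            str(mid): tuple((str(g), float(w)) for g, w in entries)
            for mid, entries in dict(self.modules).items()
        }
        object.__setattr__(self, "modules", mods)
        if self.kind == "MGL":
            required = {"ER", "HER2", "PROLIF"}
            missing = required - set(mods)
            if missing:
                raise ValueError(f"MGL {self.list_id!r} lacks modules {sorted(missing)}")
            for mid, entries in mods.items():
                zeros = [g for g, w in entries if w == 0.0]
                if zeros:
                    raise ValueError(
                        f"MGL {self.list_id!r} module {mid} has zero weights: {zeros}"
                    )


def write_gene_lists(lists: Iterable[GeneListSet], path) -> None:
    """Write one or more gene lists to a single tab-delimited file.

    Columns: list_id, kind, module_id (empty for IGL), gene_id, weight
    (empty for IGL).
    """
    rows = []
    for gl in lists:
        if gl.kind == "IGL":
            for g in gl.genes:
                rows.append((gl.list_id, "IGL", "", g, ""))
        else:
            for mid, entries in gl.modules.items():
                for g, w in entries:
                    rows.append((gl.list_id, "MGL", mid, g, w))
    pd.DataFrame(
        rows, columns=["list_id", "kind", "module_id", "gene_id", "weight"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_lists(path) -> dict[str, GeneListSet]:
    df = pd.read_csv(path, sep="\t", dtype={"list_id": str, "kind": str, "gene_id": str})
    out: dict[str, GeneListSet] = {}
    for lid, grp in df.groupby("list_id", sort=False):
        kind = grp["kind"].iloc[0]
        if kind == "IGL":
            out[str(lid)] = GeneListSet(
                list_id=str(lid), kind="IGL", genes=tuple(grp["gene_id"])
            )
        else:
            modules: dict[str, list[tuple[str, float]]] = {}
            for _, row in grp.iterrows():
                modules.setdefault(str(row["module_id"]), []).append(
                    (str(row["gene_id"]), float(row["weight"]))
                )
            out[str(lid)] = GeneListSet(
                list_id=str(lid),
                kind="MGL",
                modules={k: tuple(v) for k, v in modules.items()},
            )
    return out
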