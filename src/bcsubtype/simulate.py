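"""Synthetic multi-dataset expression compendia with known subtype truth.

The generator emulates the structure every stage of the package needs from
a real microarray compendium: four intrinsic subtypes with characteristic
ER / HER2 / proliferation / PGR module activity, subtype-independent
background genes, per-dataset location/scale batch effects on the log2
scale, optional replicate array pairs, and configurable subtype
proportions per dataset.

For each module gene g of module m in a sample s of subtype k,

    a_sm  = separation * mean[k, m] + eta_sm
    x_gs  = scale_dg * (baseline_g + sign_g * a_sm + eps_gs) + shift_dg

where a_sm is the sample's module activity (subtype mean plus biological
jitter eta shared by all genes of the module — the tumor-to-tumor
heterogeneity that keeps module scores imperfectly bimodal), eps is
Gaussian (or Student-t) gene-level noise, baseline_g a shared per-gene
level, and (shift_dg, scale_dg) per-dataset batch effects that are affine
per gene — exactly the distortion robust percentile scaling removes.
A fraction of each module's genes is negatively regulated (sign -1), so
signed module-score weights are exercised. Background genes carry no
subtype signal. Default subtype proportions (0.29, 0.10, 0.31, 0.30)
mirror the composition of typical breast-cancer consensus cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SUBTYPE_ORDER, ExpressionMatrix, GeneListSet, SubtypeAssignment

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "DEFAULT_SUBTYPE_MEANS",
    "simulate_compendium",
    "simulate_module_scores",
    "make_gene_lists",
    "module_genes",
]

#: per-subtype module activity pattern (rows BASAL/HER2/LUMA/LUMB, columns
#: ER/HER2/PROLIF/PGR), in units of the separation multiplier on the log2 axis
DEFAULT_SUBTYPE_MEANS: dict[str, tuple[float, float, float, float]] = {
    "BASAL": (-1.0, -1.0, +1.0, -1.0),
    "HER2": (-0.5, +1.0, +0.5, -1.0),
    "LUMA": (+1.0, -1.0, -1.0, +1.0),
    "LUMB": (+1.0, -1.0, +1.0, +1.0),
}

_MODULES = ("ER", "HER2", "PROLIF", "PGR")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic compendium; the seed fixes the full output."""

    n_datasets: int = 5
    samples_per_dataset: int = 150
    proportions: tuple[float, float, float, float] = (0.29, 0.10, 0.31, 0.30)
    proportions_per_dataset: tuple | None = None  # optional per-dataset override
    n_er: int = 20
    n_her2: int = 20
    n_prolif: int = 20
    n_pgr: int = 6
    n_background: int = 120
    neg_fraction: float = 0.25
    subtype_means: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MEANS))
    within_sd: float = 1.0
    module_activity_sd: float = 1.0
    gene_program_sd: float = 1.4
    sigma_batch: float = 0.5
    scale_jitter: float = 0.1
    separation: float = 2.0
    replicate_pairs: int = 0
    replicate_sd: float = 0.3
    noise: str = "gaussian"  # or "student"
    student_df: float = 4.0
    baseline_mean: float = 7.5
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        props = self._all_proportions()
        for p in props:
            if len(p) != 4 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"invalid subtype proportions {p}: must be 4 "
                                 "non-negative values summing to 1")
        for name in ("n_datasets", "samples_per_dataset", "n_er", "n_her2",
                     "n_prolif", "n_pgr", "n_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def _all_proportions(self) -> list[tuple]:
        if self.proportions_per_dataset is not None:
            if len(self.proportions_per_dataset) != self.n_datasets:
                raise ValueError("proportions_per_dataset length != n_datasets")
            return [tuple(p) for p in self.proportions_per_dataset]
        return [tuple(self.proportions)] * self.n_datasets


@dataclass
class SimulatedDataset:
    """One simulated dataset: expression, true labels, replicate pairs."""

    matrix: ExpressionMatrix
    truth: SubtypeAssignment
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)


def module_genes(cfg: SimulationConfig) -> dict[str, list[tuple[str, int]]]:
    """Deterministic gene universe: per module a list of (gene_id, sign).

    Every fourth gene of a module (when neg_fraction=0.25) is negatively
    regulated; signs are a fixed function of the index so gene lists and
    simulated data always agree.
    """
    counts = {"ER": cfg.n_er, "HER2": cfg.n_her2, "PROLIF": cfg.n_prolif,
              "PGR": cfg.n_pgr}
    period = max(2, round(1.0 / cfg.neg_fraction)) if cfg.neg_fraction > 0 else 0
    out: dict[str, list[tuple[str, int]]] = {}
    for mod, n in counts.items():
        genes = []
        for i in range(n):
            sign = -1 if (period and i % period == period - 1) else 1
            genes.append((f"{mod}_g{i:03d}", sign))
        out[mod] = genes
    return out


def background_genes(cfg: SimulationConfig) -> list[str]:
    return [f"BG_g{i:04d}" for i in range(cfg.n_background)]


def _noise(rng: np.random.Generator, size, cfg: SimulationConfig) -> np.ndarray:
    if cfg.noise == "student":
        # scaled so the marginal sd equals within_sd
        raw = rng.standard_t(cfg.student_df, size=size)
        return raw * cfg.within_sd / np.sqrt(cfg.student_df / (cfg.student_df - 2))
    return rng.normal(0.0, cfg.within_sd, size=size)


def simulate_compendium(cfg: SimulationConfig) -> list[SimulatedDataset]:
    """Generate ``cfg.n_datasets`` gene-level datasets with known truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mods = module_genes(cfg)
    bg = background_genes(cfg)
    gene_ids = [g for mod in _MODULES for g, _ in mods[mod]] + bg
    signs = np.array(
        [s for mod in _MODULES for _, s in mods[mod]] + [0] * len(bg), dtype=float
    )
    module_of = np.array(
        [mi for mi, mod in enumerate(_MODULES) for _ in mods[mod]]
        + [-1] * len(bg)
    )
    means = np.array(
        [cfg.subtype_means[s.value] for s in SUBTYPE_ORDER], dtype=float
    )  # 4 subtypes x 4 modules
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(gene_ids))
    # per-gene loading on a secondary per-module program: module genes track
    # their phenotype's activity but also carry gene-specific correlated
    # biology, so two gene lists drawn from the same module measure the
    # phenotype slightly differently (shared across datasets)
    program_loading = np.zeros(len(gene_ids))
    mask_mod = module_of >= 0
    program_loading[mask_mod] = rng.normal(
        0.0, cfg.gene_program_sd, size=int(mask_mod.sum())
    )
    props = cfg._all_proportions()

    out: list[SimulatedDataset] = []
    for d in range(cfg.n_datasets):
        did = f"D{d + 1}"
        n = cfg.samples_per_dataset
        # batch structure: a dataset-wide intensity shift/scale (array
        # brightness, chip design) plus independent per-gene components
        shift = rng.normal(0.0, cfg.sigma_batch) + rng.normal(
            0.0, cfg.sigma_batch, size=len(gene_ids)
        )
        scale = np.exp(
            rng.normal(0.0, cfg.scale_jitter)
            + rng.normal(0.0, cfg.scale_jitter, size=len(gene_ids))
        )
        subtype_idx = rng.choice(4, size=n, p=np.asarray(props[d], dtype=float))
        # per-sample module activity: subtype mean plus biological jitter
        # shared by all genes of the module (tumor-to-tumor heterogeneity;
        # this is what keeps module scores imperfectly bimodal, since purely
        # gene-level noise would average away over a module)
        activity = cfg.separation * means[subtype_idx] + rng.normal(
            0.0, cfg.module_activity_sd, size=(n, 4)
        )
        program = rng.normal(0.0, 1.0, size=(n, 4))  # secondary latent per module
        signal = np.zeros((len(gene_ids), n))
        mask = module_of >= 0
        signal[mask, :] = (
            signs[mask, None] * activity[:, module_of[mask]].T
            + program_loading[mask, None] * program[:, module_of[mask]].T
        )
        underlying = baseline[:, None] + signal + _noise(rng, (len(gene_ids), n), cfg)
        sample_ids = [f"{did}_s{i:03d}" for i in range(n)]
        labels = [SUBTYPE_ORDER[k] for k in subtype_idx]
        pairs: list[tuple[str, str]] = []
        if cfg.replicate_pairs > 0:
            n_rep = min(cfg.replicate_pairs, n)
            rep_cols = []
            for j in range(n_rep):
                u = underlying[:, j]
                a = u + rng.normal(0.0, cfg.replicate_sd, size=len(gene_ids))
                b = u + rng.normal(0.0, cfg.replicate_sd, size=len(gene_ids))
                rep_cols.extend([a, b])
                ida, idb = f"{did}_r{j:03d}a", f"{did}_r{j:03d}b"
                sample_ids.extend([ida, idb])
                labels.extend([SUBTYPE_ORDER[subtype_idx[j]]] * 2)
                pairs.append((ida, idb))
            underlying = np.column_stack([underlying] + rep_cols)
        values = scale[:, None] * underlying + shift[:, None]
        matrix = ExpressionMatrix(
            feature_ids=list(gene_ids),
            sample_ids=sample_ids,
            values=values,
            dataset_id=did,
            level="gene",
            scaled=False,
            meta={"replicate_pairs": list(pairs)},
        )
        truth = SubtypeAssignment(
            sample_ids=tuple(sample_ids), labels=tuple(labels), predictor_id="truth"
        )
        out.append(SimulatedDataset(matrix=matrix, truth=truth, replicate_pairs=pairs))
    return out


def simulate_module_scores(
    n: int,
    separation: float = 3.0,
    sd: float = 0.5,
    proportions: tuple[float, float, float, float] = (0.29, 0.10, 0.31, 0.30),
    seed: int = 0,
):
    """Draw (ER, HER2, PROLIF, PGR) scores directly from the model family.

    Scores for a sample of subtype k are Gaussian around
    ``0.5 * separation * mean[k, m]`` with standard deviation ``sd`` — i.e.
    exactly the mixture family the SCM fits. Returns (scores DataFrame,
    truth labels, component mean matrix).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    means = 0.5 * separation * np.array(
        [DEFAULT_SUBTYPE_MEANS[s.value] for s in SUBTYPE_ORDER]
    )
    k = rng.choice(4, size=n, p=np.asarray(proportions, dtype=float))
    scores = rng.normal(means[k], sd)
    df = pd.DataFrame(scores, columns=list(_MODULES),
                      index=[f"s{i:04d}" for i in range(n)])
    truth = SubtypeAssignment(
        sample_ids=tuple(df.index),
        labels=tuple(SUBTYPE_ORDER[i] for i in k),
        predictor_id="truth",
    )
    return df, truth, means


def _overlap_lists(
    genes: list, overlap: float, k: int, rng: np.random.Generator
) -> list[list]:
    """k subsets of ``genes`` with pairwise overlap fraction ``overlap``.

    Every subset keeps a shared core of the first ``overlap * m`` genes and
    draws its remaining genes from disjoint chunks of a shuffled pool, so
    the realized pairwise overlap equals the requested fraction (up to
    rounding). The subset size m is the largest for which k disjoint
    extra-chunks fit in the universe.
    """
    n = len(genes)
    denom = overlap + k * (1.0 - overlap)
    m = max(1, int(np.floor(n / denom)))
    while m > 1:
        n_core = int(round(overlap * m))
        if k * (m - n_core) <= n - n_core:
            break
        m -= 1
    n_core = int(round(overlap * m))
    n_extra = m - n_core
    core = list(genes[:n_core])
    pool = list(genes[n_core:])
    perm = rng.permutation(len(pool))
    out = []
    for i in range(k):
        chunk_idx = sorted(perm[i * n_extra : (i + 1) * n_extra])
        out.append(core + [pool[j] for j in chunk_idx])
    return out


def make_gene_lists(
    cfg: SimulationConfig,
    overlap: float = 0.7,
    seed: int = 0,
    igl_ids: tuple[str, ...] = ("S", "H", "P"),
    mgl_ids: tuple[str, ...] = ("D", "W", "HK"),
    igl_background: int = 20,
) -> tuple[dict[str, GeneListSet], dict[str, GeneListSet]]:
    """Three overlapping synthetic IGLs and MGLs over the gene universe.

    Each list keeps a shared core of ``overlap`` of its genes per module
    and fills the rest from list-specific disjoint chunks, so pairwise
    per-module overlap equals ``overlap`` up to rounding (at overlap 1 the
    lists are identical). MGL weights are the true regulation signs
    (+1/-1). MGLs carry ER/HER2/PROLIF only; the PGR phenotype is supplied
    as a single-gene module (see :func:`pgr_single_gene`).
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    if len(igl_ids) != len(mgl_ids):
        raise ValueError("need equally many IGL and MGL identifiers")
    k = len(igl_ids)
    rng = np.random.default_rng(seed)
    mods = module_genes(cfg)
    bg = background_genes(cfg)
    mgl_parts = {
        mod: _overlap_lists(mods[mod], overlap, k, rng)
        for mod in ("ER", "HER2", "PROLIF")
    }
    igl_parts = {mod: _overlap_lists(mods[mod], overlap, k, rng) for mod in _MODULES}
    bg_parts = (
        _overlap_lists(bg[: max(1, 2 * k * igl_background)], overlap, k, rng)
        if igl_background > 0
        else [[] for _ in range(k)]
    )
    igls: dict[str, GeneListSet] = {}
    mgls: dict[str, GeneListSet] = {}
    for i, (igl_id, mgl_id) in enumerate(zip(igl_ids, mgl_ids)):
        modules = {
            mod: tuple((g, float(s)) for g, s in mgl_parts[mod][i])
            for mod in ("ER", "HER2", "PROLIF")
        }
        igl_genes = [g for mod in _MODULES for g, _ in igl_parts[mod][i]]
        igl_genes.extend(bg_parts[i][:igl_background])
        igls[igl_id] = GeneListSet(list_id=igl_id, kind="IGL", genes=tuple(igl_genes))
        mgls[mgl_id] = GeneListSet(list_id=mgl_id, kind="MGL", modules=modules)
    return igls, mgls


def pgr_single_gene(cfg: SimulationConfig) -> str:
    """The fixed single-gene PGR module of the synthetic universe."""
    return module_genes(cfg)["PGR"][0][0]
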