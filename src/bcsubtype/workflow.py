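"""End-to-end concordance experiment on a synthetic compendium.

Orchestrates the full design the package exists to study: simulate a
multi-dataset compendium with known truth, train a reference nearest-
centroid model on a held-out cohort, build a consensus set on each training
cohort with the five-predictor panel, train the consensus-based SSP/SCM/STG
suites, apply every model to every validation cohort, and aggregate pairwise
kappa statistics into the comparison groups (gene list differs / consensus
set differs / both differ / predictor types differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .concordance import ComparisonDesign, KappaResult, aggregate_concordance, cohens_kappa
from .consensus import ConsensusSet, build_consensus, default_panel, train_cs_suite
from .core import SubtypeAssignment
from .modules import score_matrix
from .preprocess import robust_scale
from .simulate import (
    SimulationConfig,
    make_gene_lists,
    pgr_single_gene,
    simulate_compendium,
)
from .ssp import train_ssp

__all__ = ["ExperimentResult", "run_concordance_experiment"]


@dataclass
class ExperimentResult:
    """Everything the end-to-end experiment produced."""

    consensus_sets: dict[str, ConsensusSet]
    assignments: dict[tuple[str, str, str, str], SubtypeAssignment]  # (type, gl, cs, V)
    comparisons: list[tuple[ComparisonDesign, KappaResult]]
    intra: dict  # per predictor type: aggregate_concordance output
    inter: dict  # inter-type aggregate
    truth_kappa: dict = field(default_factory=dict)


def run_concordance_experiment(
    n_training: int = 5,
    n_validation: int = 6,
    samples_per_dataset: int = 500,
    overlap: float = 0.7,
    separation: float = 2.0,
    predictor_types: tuple[str, ...] = ("SSP", "SCM"),
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> ExperimentResult:
    """Run the consensus-training / cross-validation concordance design.

    Simulates ``n_training + n_validation + 1`` datasets (the extra one
    trains the reference model used in the consensus panel), builds one
    consensus set per training cohort, trains the model suites on each, and
    compares predictions of all model pairs on every validation cohort.
    """
    base = config or SimulationConfig()
    cfg = replace(
        base,
        n_datasets=n_training + n_validation + 1,
        samples_per_dataset=samples_per_dataset,
        separation=separation,
        seed=seed,
    )
    datasets = simulate_compendium(cfg)
    ref_ds = datasets[0]
    training = datasets[1 : 1 + n_training]
    validation = datasets[1 + n_training :]
    igls, mgls = make_gene_lists(cfg, overlap=overlap, seed=seed + 1)
    pgr = pgr_single_gene(cfg)
    igl_list = list(igls.values())
    mgl_list = list(mgls.values())

    # reference predictor for the panel: supervised centroids on the held-out
    # cohort with its true labels (the "published reference model" role)
    ref_model = train_ssp(robust_scale(ref_ds.matrix), ref_ds.truth, igl_list[0])

    consensus_sets: dict[str, ConsensusSet] = {}
    suites: dict[str, dict] = {}
    for ds in training:
        panel = default_panel(ds.matrix, ref_model, mgl_list, seed=seed, pgr_gene=pgr)
        cs = build_consensus(panel, source_dataset_id=ds.matrix.dataset_id)
        consensus_sets[ds.matrix.dataset_id] = cs
        suites[ds.matrix.dataset_id] = train_cs_suite(
            cs, ds.matrix, igl_list, mgl_list, seed=seed, pgr_gene=pgr
        )

    # apply every model to every validation cohort, caching scores per MGL
    assignments: dict[tuple[str, str, str, str], SubtypeAssignment] = {}
    truth_kappa: dict[tuple[str, str, str], float] = {}
    for vds in validation:
        vid = vds.matrix.dataset_id
        scaled_v = robust_scale(vds.matrix)
        score_cache = {
            mgl.list_id: score_matrix(vds.matrix, mgl, scale=True, pgr_gene=pgr)
            for mgl in mgl_list
        }
        for cs_id, suite in suites.items():
            for (ptype, gl_id), model in suite.items():
                if ptype not in predictor_types:
                    continue
                if ptype == "SSP":
                    from .ssp import predict_ssp

                    a = predict_ssp(model, scaled_v)
                elif ptype == "SCM":
                    from .scm import predict_scm

                    a = predict_scm(model, score_cache[gl_id])[0]
                else:
                    from .stg import predict_stg

                    a = predict_stg(model, score_cache[gl_id])[0]
                assignments[(ptype, gl_id, cs_id, vid)] = a
                truth_kappa[(ptype, gl_id, cs_id, vid)] = cohens_kappa(
                    vds.truth, a
                ).kappa

    # pairwise comparisons on each validation cohort
    comparisons: list[tuple[ComparisonDesign, KappaResult]] = []
    keys = sorted(assignments)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            if ka[3] != kb[3]:
                continue  # same validation cohort only
            if ka[:3] == kb[:3]:
                continue
            design = ComparisonDesign(
                type_a=ka[0], type_b=kb[0],
                gene_list_a=ka[1], gene_list_b=kb[1],
                cs_a=ka[2], cs_b=kb[2],
                validation_dataset=ka[3],
            )
            comparisons.append((design, cohens_kappa(assignments[ka], assignments[kb])))

    intra: dict[str, dict] = {}
    for ptype in predictor_types:
        subset = [
            (d, r)
            for d, r in comparisons
            if d.type_a == ptype and d.type_b == ptype
        ]
        if subset:
            intra[ptype] = aggregate_concordance(subset)
    inter_subset = [(d, r) for d, r in comparisons if d.type_a != d.type_b]
    inter = aggregate_concordance(inter_subset) if inter_subset else {}

    return ExperimentResult(
        consensus_sets=consensus_sets,
        assignments=assignments,
        comparisons=comparisons,
        intra=intra,
        inter=inter,
        truth_kappa=truth_kappa,
    )
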