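import numpy as np
import pytest

from bcsubtype.core import ExpressionMatrix, Subtype, SubtypeAssignment
from bcsubtype.simulate import SimulationConfig, make_gene_lists, pgr_single_gene, simulate_compendium


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Small 3-dataset compendium configuration used across tests."""
    return SimulationConfig(n_datasets=3, samples_per_dataset=120, seed=11)


@pytest.fixture(scope="session")
def compendium(small_cfg):
    return simulate_compendium(small_cfg)


@pytest.fixture(scope="session")
def gene_lists(small_cfg):
    igls, mgls = make_gene_lists(small_cfg, overlap=0.7, seed=12)
    return igls, mgls


@pytest.fixture(scope="session")
def pgr_gene(small_cfg):
    return pgr_single_gene(small_cfg)


@pytest.fixture(scope="session")
def panel_cfg() -> SimulationConfig:
    """Well-separated compendium for consensus-panel and suite tests."""
    return SimulationConfig(n_datasets=3, samples_per_dataset=200,
                            separation=3.0, seed=11)


@pytest.fixture(scope="session")
def panel_compendium(panel_cfg):
    return simulate_compendium(panel_cfg)


@pytest.fixture()
def toy_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    return ExpressionMatrix(
        feature_ids=genes,
        sample_ids=samples,
        values=rng.normal(7, 1, size=(10, 6)),
        dataset_id="toy",
    )


def random_assignment(rng, sample_ids, labels=None) -> SubtypeAssignment:
    labels = labels or list(Subtype)
    idx = rng.integers(0, len(labels), size=len(sample_ids))
    return SubtypeAssignment(
        sample_ids=tuple(sample_ids),
        labels=tuple(labels[i] for i in idx),
        predictor_id="rnd",
    )
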