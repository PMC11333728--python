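import numpy as np
import pytest

from crossdx.diffexpr import ExpressionStudy
from crossdx.synthdata import SimulationConfig, generate_two_disease_studies


@pytest.fixture(scope="session")
def small_sim():
    """Small planted two-disease simulation shared across tests."""
    cfg = SimulationConfig(
        seed=42, n_genes=600, n_shared_up=40, n_shared_down=15,
        n_specific_per_disease=20, samples_per_group=[(12, 12)] * 4,
    )
    studies1, studies2, truth = generate_two_disease_studies(cfg)
    return cfg, studies1, studies2, truth


@pytest.fixture
def tiny_study():
    """Four genes, 3 case vs 2 control, hand-checkable intensities."""
    rng = np.random.default_rng(5)
    matrix = 2.0 ** rng.normal(7, 1, size=(4, 5))
    return ExpressionStudy(
        gene_ids=["g1", "g2", "g3", "g4"],
        matrix=matrix,
        groups=["case"] * 3 + ["control"] * 2,
        study_id="tiny",
    )
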