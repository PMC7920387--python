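import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tspath.expression import ExpressionMatrix, PhenotypeTable
from tspath.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples (2 tumor, 2 control), positive scale."""
    groups = PhenotypeTable(groups={"T1": "tumor", "T2": "tumor",
                                    "C1": "control", "C2": "control"})
    values = np.array([
        [4.0, 4.0, 2.0, 2.0],   # logFC = 1
        [2.0, 2.0, 2.0, 2.0],   # logFC = 0
        [1.0, 1.0, 4.0, 4.0],   # logFC = -2
        [8.0, 8.0, 1.0, 1.0],   # logFC = 3
    ])
    return ExpressionMatrix(genes=["gA", "gB", "gC", "gD"],
                            samples=["T1", "T2", "C1", "C2"],
                            values=values, groups=groups)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulation shared across tests (read-only)."""
    return simulate_all(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A fast, smaller scenario for end-to-end file-based tests."""
    strengths = {f"drug-{i:02d}": 0.9 for i in range(1, 4)}
    strengths.update({f"drug-{i:02d}": 0.0 for i in range(4, 9)})
    return SimulationConfig(
        n_genes=120, n_tumor=8, n_control=6, n_pathways=3, pathway_size=10,
        n_decoy_pathways=3, n_seed_genes=4, n_drugs=8, k_instances=2,
        reversal_strengths=strengths, rng_seed=5,
    )
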