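import numpy as np
import pytest

from epimsap import PairedBandMatrix, PopulationMap, SyntheticConfig, generate


@pytest.fixture
def toy_bands() -> PairedBandMatrix:
    """3 individuals x 4 loci covering all four methylation types."""
    # columns: type I everywhere, mixed, mixed, type IV everywhere
    H = np.array([[1, 0, 1, 0], [1, 1, 0, 0], [1, 0, 1, 0]])
    M = np.array([[1, 1, 0, 0], [1, 1, 1, 0], [1, 0, 0, 0]])
    return PairedBandMatrix(
        individual_ids=["a", "b", "c"],
        locus_ids=["E1/M1_100", "E1/M1_150", "E2/M2_200", "E2/M2_250"],
        H=H,
        M=M,
    )


@pytest.fixture
def toy_pops() -> PopulationMap:
    return PopulationMap(assignments={"a": "G1", "b": "G1", "c": "G2"})


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default 5x10 regional design (50 x 551)."""
    return generate(SyntheticConfig(seed=20260))


@pytest.fixture(scope="session")
def small_dataset():
    """Small 3-group dataset reused across modules."""
    cfg = SyntheticConfig(
        seed=77,
        n_groups=3,
        n_per_group=5,
        group_names=("A", "B", "C"),
        primer_pairs={"E1/M1": 20, "E2/M2": 20},
        group_to_subpop={"A": 1, "B": 1, "C": 2},
        dirichlet_alpha=3.0,
    )
    return generate(cfg)
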