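import warnings

import numpy as np
import pytest

import vesicleshift as vs

# sklearn's MCD emits benign determinant warnings on near-degenerate
# subsets; they are not part of any contract under test
warnings.filterwarnings("ignore", message="Determinant has increased")


@pytest.fixture(scope="session")
def small_sim():
    """A small two-condition simulation with relocated proteins and outliers."""
    cfg = vs.SimulationConfig(n_proteins=400, reloc_fraction=0.05, seed=3)
    datasets, markers, truth = vs.simulate_dataset(cfg)
    return cfg, datasets, markers, truth


@pytest.fixture(scope="session")
def normalised_sim(small_sim):
    cfg, datasets, markers, truth = small_sim
    control = vs.normalise_rows(datasets["control"])
    treatment = vs.normalise_rows(datasets["treatment"])
    return cfg, control, treatment, markers, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_scheme():
    return vs.FractionScheme(
        fraction_ids=("F1", "F2", "F3"),
        replicate_ids=("R1", "R2"),
        condition_id="control",
    )
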