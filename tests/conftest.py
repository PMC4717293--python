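import numpy as np
import pytest

from qvasc.synthetic import (
    AnimalTruth,
    CohortSpec,
    make_phantom,
    study_defaults_24mo,
    sample_animal_truths,
    synth_dsc,
    synth_steady_state,
)


@pytest.fixture(scope="session")
def phantom_small():
    """Compact phantom shared across tests (same grid as the default DSC run)."""
    return make_phantom((24, 24, 6))


@pytest.fixture(scope="session")
def scatter_free_spec():
    """Default effect table, no biological scatter, no noise."""
    return study_defaults_24mo(seed=1, scatter_sigma=0.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def control_truth(scatter_free_spec):
    rng = np.random.default_rng(0)
    return AnimalTruth(
        animal_id="ctrl",
        genotype="control",
        region_values=sample_animal_truths(scatter_free_spec, "control", rng),
        bat_s=30.0,
        aif=scatter_free_spec.aif,
    )


@pytest.fixture(scope="session")
def noiseless_dsc(phantom_small, control_truth):
    """One noiseless dynamic series on the compact phantom."""
    return synth_dsc(phantom_small, control_truth, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_steady_matched(phantom_small, control_truth):
    """Noiseless steady-state volumes with GE on the SE grid (exactness path)."""
    return synth_steady_state(phantom_small, control_truth, noise_sigma=0.0, ge_upsample=1)
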