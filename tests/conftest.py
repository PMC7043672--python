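import numpy as np
import pytest

from dualpred import ModelVariant, ParameterSet
from dualpred.abc import SMCConfig, default_prior, run_abc_smc
from dualpred.datagen import ExperimentDesign, NoiseModel, generate_dataset


@pytest.fixture(scope="session")
def final_variant():
    """The winning model configuration: three prey phenotypes, signal
    from Bdellovibrio-prey interaction, growth-coupled back conversion,
    saturating Bdellovibrio attack, non-saturating phage attack."""
    return ModelVariant()


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def synthetic_dataset(final_variant, default_params):
    """Default 48-h, 2-h-interval, triplicate, four-condition dataset."""
    return generate_dataset(
        final_variant, default_params, ExperimentDesign(), NoiseModel(seed=1)
    )


@pytest.fixture(scope="session")
def n3_fit(final_variant, synthetic_dataset):
    """Shared ABC-SMC fit of the final variant to the synthetic data
    (used by the recovery and prediction checks)."""
    cfg = SMCConfig(n_particles=200, max_generations=8, seed=11)
    return run_abc_smc(
        [final_variant], default_prior(final_variant), synthetic_dataset, cfg
    )

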