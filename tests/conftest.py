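import numpy as np
import pytest

from holostim.config import AnalysisConfig, GeneratorConfig, ModelConfig


@pytest.fixture(scope="session")
def small_model_config() -> ModelConfig:
    """Coarse grid for fast solver tests (kernels still resolvable)."""
    return ModelConfig(
        domain_size=256.0,
        grid_spacing=16.0,
        n_orientations=4,
        sigma_e_narrow=20.0,
        sigma_i_narrow=20.0,
        sigma_e_broad=60.0,
        sigma_i_broad=50.0,
    )


@pytest.fixture(scope="session")
def default_model_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_generator_config() -> GeneratorConfig:
    return GeneratorConfig(n_cells_per_plane=150, n_ensembles=4, random_seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_generator_config):
    from holostim.synth import simulate

    return simulate(small_generator_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
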