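import numpy as np
import pytest

from habfish import (
    HabitatGenConfig,
    PipelineConfig,
    default_species_params,
    generate_landscape,
    run_pipeline,
)


@pytest.fixture(scope="session")
def gen_config():
    return HabitatGenConfig(seed=11)


@pytest.fixture(scope="session")
def landscape(gen_config):
    return generate_landscape(gen_config)


@pytest.fixture(scope="session")
def species_params():
    return default_species_params()


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the default synthetic demo, shared by
    ensemble/validation/manifest tests."""
    out = tmp_path_factory.mktemp("demo")
    cfg = PipelineConfig({"output_dir": str(out), "seed": 7})
    manifest = run_pipeline(cfg)
    return cfg, manifest, out


def random_binary_grid(rng, n=32, p_habitat=0.3, p_land=0.2):
    """Random water mask + habitat subset as value arrays (1/0, NaN on land)."""
    water = rng.random((n, n)) > p_land
    hab = (rng.random((n, n)) < p_habitat) & water
    hab_values = np.where(water, hab.astype(float), np.nan)
    return water.astype(float), hab_values
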