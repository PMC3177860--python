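import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests-local oracles module

from warmcool.synthetic import (
    ChipSetConfig,
    ImagingConfig,
    generate_chip_set,
    generate_imaging_experiment,
)


@pytest.fixture(scope="session")
def chipset_large_beta():
    """Chip set whose warm/cool majority follows sign(R_LM) deterministically."""
    return generate_chip_set(ChipSetConfig(beta=1e6, seed=7))


@pytest.fixture(scope="session")
def small_imaging():
    """A fast, small imaging session (+ truth) for pipeline unit tests."""
    cfg = ImagingConfig(grid_size=64, n_patches=2, patch_diameter=12,
                        coherent_length=18, n_blocks=4, pattern_jitter=0.5,
                        seed=5)
    return generate_imaging_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_imaging():
    """Artifact-free session: no ongoing activity, vessels, or movement.

    A vanishing camera noise (1e-5, two orders below the responses) keeps
    the control-map threshold above float rounding error."""
    cfg = ImagingConfig(grid_size=64, n_patches=2, patch_diameter=12,
                        coherent_length=18, n_blocks=3, seed=9,
                        noise_sd=1e-5, coherent_sd=0.0, vessel_amplitude=0.0,
                        jitter_max=0)
    return generate_imaging_experiment(cfg)


@pytest.fixture(scope="session")
def exact_imaging():
    """Strictly zero-noise session: maps equal the inserted patterns."""
    cfg = ImagingConfig(grid_size=64, n_patches=2, patch_diameter=12,
                        coherent_length=18, n_blocks=2, seed=9,
                        noise_sd=0.0, coherent_sd=0.0, vessel_amplitude=0.0,
                        jitter_max=0)
    return generate_imaging_experiment(cfg)
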