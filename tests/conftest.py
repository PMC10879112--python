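"""Shared fixtures: a small optical configuration and simulated stacks.

The unit tests run on reduced field sizes (256-pixel camera grids, a
handful of beads) so the whole suite stays fast; the acceptance tests use
the full-size conditions.
"""

import numpy as np
import pytest

import incsim as ic


@pytest.fixture(scope="session")
def config():
    return ic.OpticalConfig()


@pytest.fixture(scope="session")
def small_bead_phantom(config):
    return ic.generate_bead_phantom(
        8, (256, 256), config.sample_pixel, min_separation=2000.0, seed=7
    )


@pytest.fixture(scope="session")
def bio12_sequence():
    # 320 SLM px at 52 nm project onto 256 camera px at 65 nm
    return ic.build_repertoire("bio12", (320, 320), 4.0)


@pytest.fixture(scope="session")
def noisefree_stack(small_bead_phantom, bio12_sequence, config):
    return ic.simulate_acquisition(
        small_bead_phantom, bio12_sequence, config,
        ic.NoiseModel(peak_photons=0.0, read_sigma=0.0, seed=0),
    )


@pytest.fixture(scope="session")
def noisy_stack(small_bead_phantom, bio12_sequence, config):
    return ic.simulate_acquisition(
        small_bead_phantom, bio12_sequence, config,
        ic.NoiseModel(peak_photons=1e4, read_sigma=2.0, seed=11),
    )
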