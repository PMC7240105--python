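import warnings

import pytest

from competage.pipeline import prepare_points
from competage.simulate import SimulationConfig, simulate_plate


def small_config(**overrides) -> SimulationConfig:
    """A fast 17-well plate: 8 references, 3 strains x 2 replicates,
    controls and a blank, 4 sampling days, 6 outgrowth reads."""
    base = dict(
        seed=0,
        n_reference=8,
        n_mutant_strains=3,
        replicates_per_strain=2,
        n_rfp_monoculture=1,
        n_cfp_monoculture=1,
        n_blank=1,
        days=(0.0, 3.0, 7.0, 11.0),
        hours=(0.0, 2.0, 4.0, 6.0, 8.0, 12.0),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_small_plate():
    """Noise-free small plate: no measurement noise, batch offsets, mixing
    jitter or growth-rate variation (log-ratios exactly linear)."""
    cfg = small_config(seed=5, sigma_log=0.0, c_sd=0.0, a_jitter_sd=0.0, sigma_log_g=0.0)
    return simulate_plate(cfg)


@pytest.fixture(scope="session")
def noisy_small_plate():
    return simulate_plate(small_config(seed=9))


@pytest.fixture(scope="session")
def noisy_small_points(noisy_small_plate):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        points, _ = prepare_points(noisy_small_plate.measurements, noisy_small_plate.layout)
    return points
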