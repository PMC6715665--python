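"""Shared fixtures: simulated datasets reused across test modules."""

import numpy as np
import pytest

from annulodyn import build_protocol, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default-protocol dataset, seed 1 (noisy, jittered)."""
    protocol = build_protocol({"seed": 1})
    return protocol, simulate_dataset(protocol)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, jitter-free dataset for exact recovery checks."""
    protocol = build_protocol(
        {
            "seed": 7,
            "distance_noise_sd_mm": 0.0,
            "analogue_noise_sd": {"lvp": 0.0, "aop": 0.0, "ecg": 0.0, "strain": 0.0},
            "rr_jitter_sd_s": 0.0,
        }
    )
    return protocol, simulate_dataset(protocol)


@pytest.fixture(scope="session")
def static_dataset():
    """Static annulus: no motion, no noise — every frame identical."""
    protocol = build_protocol(
        {
            "seed": 3,
            "n_beats": 6,
            "base_radius_mm": 12.0,
            "radius_amplitude_mm": 0.0,
            "ellipticity_max": 1.0,
            "wobble_amplitude_mm": 0.0,
            "force_amplitude_N": {"LN": 0.0, "RN": 0.0, "LR": 0.0},
            "distance_noise_sd_mm": 0.0,
            "analogue_noise_sd": {"lvp": 0.0, "aop": 0.0, "ecg": 0.0, "strain": 0.0},
            "rr_jitter_sd_s": 0.0,
        }
    )
    return protocol, simulate_dataset(protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
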