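import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ageadapt as aa

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design() -> aa.StudyDesign:
    return aa.StudyDesign()


@pytest.fixture(scope="session")
def noiseless_normalization(design) -> aa.RatingDataset:
    """Exact renormalization data (k = 0.1): shifts +2.2 / 0 / -0.8."""
    cfg = aa.SimulationConfig(
        design=design,
        truth_model="normalization",
        truth_params=aa.NormalizationParams(gain_k=0.1, norm_age=design.norm_age),
        rating_noise_sd=0.0,
        seed=11,
    )
    return aa.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_repulsion(design) -> aa.RatingDataset:
    """Exact constrained-repulsion data (A = 2.4, sigma = 20)."""
    cfg = aa.SimulationConfig(
        design=design,
        truth_model="repulsion",
        truth_params=aa.GDRepulsionParams(amplitude_A=2.4, sigma=20.0),
        rating_noise_sd=0.0,
        seed=12,
    )
    return aa.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_normalization(design) -> aa.RatingDataset:
    """Default study conditions under renormalization truth."""
    cfg = aa.SimulationConfig(design=design, truth_model="normalization", seed=13)
    return aa.generate_dataset(cfg)


def make_dataset(pre, after, condition="middle"):
    """Build a dataset from raw arrays for targeted fitting tests."""
    return aa.RatingDataset(
        [
            aa.AftereffectPoint(condition, f"f{i}", float(x), float(x + y))
            for i, (x, y) in enumerate(zip(np.asarray(pre), np.asarray(after)))
        ]
    )
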