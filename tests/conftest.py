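import numpy as np
import pytest

from thermofusion import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Clean 20+20-patient cohort at 32x32 with moderate lesion contrast."""
    config = SyntheticConfig(
        n_healthy=20, n_sick=20, image_height=32, image_width=32,
        hotspot_delta_t=2.0, pixel_noise_sd=0.3, clinical_effect=0.5, seed=11,
    )
    studies, records = generate_cohort(config)
    return config, studies, records


@pytest.fixture()
def clean_study(small_cohort):
    _, studies, _ = small_cohort
    return studies[0].copy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
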