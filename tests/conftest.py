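import pytest

from mycoflux import SyntheticConfig, simulate_all


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale study: fast enough for unit tests, same structure."""
    return SyntheticConfig(
        n_plant_transcripts=600,
        n_fungal_transcripts=400,
        n_planted_pos=5,
        n_planted_neg=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def study(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def noisefree_study():
    cfg = SyntheticConfig(
        n_plant_transcripts=300,
        n_fungal_transcripts=200,
        n_planted_pos=3,
        n_planted_neg=3,
        isotope_noise_sd=0.0,
        growth_noise=0.0,
        seed=7,
    )
    return simulate_all(cfg)
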