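import pytest

from twinpillars.pillars import code_dataset
from twinpillars.synth import GeneratorConfig, OutcomeModel, generate_registry


@pytest.fixture(scope="session")
def small_registry():
    """Raw synthetic registry at reduced scale, with missingness."""
    cfg = GeneratorConfig(n_mz_pairs=400, n_dz_pairs=400, seed=42)
    return generate_registry(cfg)


@pytest.fixture(scope="session")
def small_coded(small_registry):
    return code_dataset(small_registry)


@pytest.fixture(scope="session")
def clean_config():
    """Generator settings with no missingness, no rounding, no confounds."""
    return GeneratorConfig(
        n_mz_pairs=1500,
        n_dz_pairs=1500,
        seed=7,
        outcomes={
            "log_bmi": OutcomeModel(
                mean=3.25, resid_sd=0.19, resid_ace=(0.6, 0.2, 0.2)
            ),
            "sqrt_phq": OutcomeModel(
                mean=0.62, resid_sd=0.60, resid_ace=(0.35, 0.05, 0.60)
            ),
        },
        missing_rates={},
        round_raw=False,
    )


@pytest.fixture(scope="session")
def clean_coded(clean_config):
    return code_dataset(generate_registry(clean_config))
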