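import numpy as np
import pytest

from scfc.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Small, fast cohort: 40 nodes, 8 hubs, 3+3+2 subjects.

    Edge probabilities are raised so the small networks stay dense enough
    for coupling (>= 10 qualifying edges per subject).
    """
    return GeneratorConfig(
        n_nodes=40,
        n_cortical=32,
        n_subcortical=8,
        n_hubs=8,
        group_sizes={"NC": 3, "MCI": 3, "AD": 2},
        p_rich=0.6,
        p_feeder=0.25,
        p_local=0.15,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale synthetic cohort at generator defaults (97 subjects)."""
    return generate_cohort(GeneratorConfig(seed=2024))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
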