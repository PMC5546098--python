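import pytest

from sensnet import UniverseConfig, generate_universe


@pytest.fixture(scope="session")
def small_universe():
    """300-chemical default-regime universe shared by read-only tests."""
    config = UniverseConfig(n_chemicals=300, n_clusters=5, seed=11)
    chems, studies, truth = generate_universe(config)
    return config, chems, studies, truth


@pytest.fixture(scope="session")
def purity_universe():
    """10 planted clusters with 95% label purity (alternating majorities),
    no background chemicals; the parameter-recovery regime."""
    config = UniverseConfig(
        n_chemicals=500, n_clusters=10, seed=7,
        per_cluster_prevalence=[0.95, 0.05] * 5,
        background_fraction=0.0, label_bits=0)
    chems, studies, truth = generate_universe(config)
    return config, chems, studies, truth
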