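import numpy as np
import pytest

from provblup.simulate import SimulationConfig, TraitDef, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A compact single-site trial: 5 provenances x 6 mothers x 6 offspring."""
    cfg = SimulationConfig.from_targets(
        0.3,
        0.2,
        n_provenances=5,
        mothers_per_provenance=6,
        offspring_per_mother=6,
        replicates=6,
        sets_per_replicate=2,
        n_controls=2,
        seed=42,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def two_trait_trial():
    """Two genetically correlated traits (r_G = 0.6) on one site."""
    cfg = SimulationConfig.from_targets(
        0.35,
        0.0001,
        n_provenances=4,
        mothers_per_provenance=15,
        offspring_per_mother=8,
        replicates=8,
        sets_per_replicate=2,
        n_controls=2,
        traits=(TraitDef("t1"), TraitDef("t2")),
        trait_genetic_corr=((1.0, 0.6), (0.6, 1.0)),
        seed=77,
    )
    return simulate_trial(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
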