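import numpy as np
import pytest

import avgmodel as am


@pytest.fixture(scope="session")
def abc():
    return am.GeneUniverse.from_string("ABC")


@pytest.fixture(scope="session")
def jeps():
    return am.GeneUniverse.from_string("JEPS")


@pytest.fixture(scope="session")
def fig1_means():
    """Exact mean table of the six-node example network (8 genotypes)."""
    return am.network_means(am.fig1_fixture())


def random_mean_table(universe: am.GeneUniverse, rng: np.random.Generator) -> am.MeanTable:
    return am.MeanTable(universe, rng.uniform(1.0, 10.0, size=2**universe.n))


@pytest.fixture(scope="session")
def synthetic_jeps():
    """A replicated noisy 4-gene dataset with known averaging coefficients."""
    universe = am.GeneUniverse.from_string("JEPS")
    spec = am.ModelSpec("averaging", universe)
    rng = np.random.default_rng(42)
    true = am.CoefficientVector(spec, 4.0, rng.normal(0.0, 1.0, len(spec.terms)))
    cfg = am.SyntheticDataConfig(
        spec=spec,
        coefficients=true,
        residual_sd=0.4,
        n_replicates=4,
        random_sds={"replicate": 0.3, "flat": 0.2, "pot": 0.1},
        obs_per_pot=2,
        seed=2024,
    )
    return cfg, true, am.generate_replicated_data(cfg)
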