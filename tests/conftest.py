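import numpy as np
import pandas as pd
import pytest

from nsdgrn.simulate import SyntheticSpec, generate_species


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    """The default synthetic study conditions, seed 7."""
    return SyntheticSpec(rng_seed=7)


@pytest.fixture(scope="session")
def default_species(default_spec):
    """One generated pseudo-species under the default conditions (reused)."""
    return generate_species(default_spec, "An")


@pytest.fixture(scope="session")
def null_species():
    """A dataset with no planted differential signal (type-I calibration)."""
    spec = SyntheticSpec(rng_seed=11, deg_up_fraction=0.0, deg_down_fraction=0.0)
    return generate_species(spec, "null")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_fpkm(rng, n_genes=20, n_samples=4, prefix="S"):
    values = rng.lognormal(2.0, 1.0, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"{prefix}{j + 1}" for j in range(n_samples)],
    )
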