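import numpy as np
import pandas as pd
import pytest

from lipidindex import (
    FunctionalLipidModel,
    load_index_library,
    parse_profile,
    worked_toy_profile,
)
from lipidindex.simulate import TEMPLATE_POOL


@pytest.fixture(scope="session")
def library():
    return load_index_library()


@pytest.fixture(scope="session")
def toy_study():
    return worked_toy_profile()


@pytest.fixture(scope="session")
def toy_model(toy_study):
    return FunctionalLipidModel(toy_study.abundance, toy_study.groups)


@pytest.fixture(scope="session")
def toy_results(toy_model):
    return toy_model.fit("EXP", "CTRL")


@pytest.fixture(scope="session")
def template_records():
    names = [n for n, _ in TEMPLATE_POOL]
    return names, parse_profile(names).records


def random_profile(rng, names, min_species=5):
    """A random sub-profile of the template pool with lognormal abundances
    and occasional exact zeros."""
    k = rng.integers(min_species, len(names) + 1)
    chosen = list(rng.choice(names, size=k, replace=False))
    values = rng.lognormal(mean=1.0, sigma=1.5, size=k)
    zero = rng.random(k) < 0.1
    values[zero] = 0.0
    return dict(zip(chosen, values))


def profile_to_frame(profile):
    return pd.DataFrame({"S1": pd.Series(profile, dtype=float)})
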