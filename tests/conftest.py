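import numpy as np
import pytest

from hetcheck.fixtures import FixtureSpec, generate_site_profiles, generate_tree
from hetcheck.models import (
    ExchangeabilityMatrix,
    FrequencyProfile,
    HomogeneousModel,
    discrete_gamma_rates,
)
from hetcheck.treeio import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20241223)


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);")


@pytest.fixture
def poisson_uniform_g1():
    """Poisson exchangeabilities, uniform frequencies, no rate variation."""
    return HomogeneousModel(
        ExchangeabilityMatrix.poisson(),
        FrequencyProfile.uniform(),
        discrete_gamma_rates(1.0, 1),
    )


@pytest.fixture
def gamma4():
    return discrete_gamma_rates(1.0, 4)


@pytest.fixture
def small_coalescent_tree():
    return generate_tree(FixtureSpec(n_taxa=12, tree_style="coalescent", seed=11))


@pytest.fixture
def sparse_profiles():
    return generate_site_profiles(40, "dirichlet:0.1", 17)
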