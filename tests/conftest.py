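import numpy as np
import pytest

from spinblock import SiteOrdering, build_hamiltonian_csf, make_preset

FIG6_PARAMS = {"J_AB": -150.0, "J_AC": -20.0}


@pytest.fixture(scope="session")
def isosceles_model():
    """3-site s=3/2 isosceles triangle with the strongly coupled AB edge."""
    return make_preset("isosceles", 3, FIG6_PARAMS)


@pytest.fixture(scope="session")
def quartet_abc(isosceles_model):
    """Quartet (S=3/2) Hamiltonian in the ABC site-separated ordering."""
    return build_hamiltonian_csf(
        isosceles_model, SiteOrdering.identity(3), twice_S=3
    )


@pytest.fixture(scope="session")
def quartet_acb(isosceles_model):
    return build_hamiltonian_csf(
        isosceles_model,
        SiteOrdering.from_labels("ACB", isosceles_model),
        twice_S=3,
    )


@pytest.fixture(scope="session")
def dimer_singlet():
    """Singlet Hamiltonian of the two-site s=3/2 cluster, site-separated."""
    model = make_preset("dimer", 3, {"J": -1.0})
    return build_hamiltonian_csf(model, SiteOrdering.identity(2), twice_S=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
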