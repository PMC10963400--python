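import numpy as np
import pytest

from eeguq.forward import assemble_leadfield
from eeguq.gpc import GPCConfig, fit_gpc
from eeguq.model import (
    default_model,
    default_priors,
    generate_montage,
    generate_source_spaces,
    standard_conductivities,
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def montage(model):
    return generate_montage(model, 80, 110.0)


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def sigma_st(priors):
    return standard_conductivities(priors)


@pytest.fixture(scope="session")
def spaces_small(model):
    """3 depths x 8 sources, mixed orientations, plus the paired dual grid."""
    return generate_source_spaces(model, [(5.0, 8), (15.0, 8), (25.0, 8)], "mixed", 1.0, seed=1)


@pytest.fixture(scope="session")
def sources_mini(model):
    """Three sources spanning shallow/mid/deep, for surrogate tests."""
    primary, _ = generate_source_spaces(model, [(5.0, 1), (15.0, 1), (30.0, 1)], "mixed", 1.0, seed=2)
    return primary


@pytest.fixture(scope="session")
def surrogate_mini(model, montage, priors, sources_mini):
    """Default-order surrogate on the three-source mini space."""
    fwd = lambda s: assemble_leadfield(model, s, sources_mini, montage)  # noqa: E731
    return fit_gpc(fwd, priors, GPCConfig(seed=3))


@pytest.fixture(scope="session")
def forward_mini(model, montage, sources_mini):
    def fwd(sigma):
        return assemble_leadfield(model, sigma, sources_mini, montage)

    return fwd
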