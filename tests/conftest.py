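import numpy as np
import pytest

from lungplast.simulate import (
    default_study_design,
    simulate_kras_panel,
    simulate_reference_panels,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 2,000 genes x 9 samples in three groups."""
    return simulate_study(default_study_design(seed=7))


@pytest.fixture(scope="session")
def panels():
    """Default reference panels for signature derivation."""
    return simulate_reference_panels(seed=7)


@pytest.fixture(scope="session")
def kras_panel():
    """Default oncogene-module cell-line panel (1,000-gene module, 3 states)."""
    return simulate_kras_panel(seed=7)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20240917)
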