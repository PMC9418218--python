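import warnings

import numpy as np
import pytest

from fracbioheat import (
    MATERIALS,
    SHAPES,
    InversionSettings,
    NanofluidMixture,
    TherapyParams,
)


@pytest.fixture(autouse=True)
def _no_convergence_warnings():
    """Durbin slow-convergence warnings are informational in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def blood():
    return MATERIALS["blood"]


@pytest.fixture
def gold_platelet_mix():
    """Default therapeutic mixture: 4% gold platelets in blood."""
    return NanofluidMixture(
        base=MATERIALS["blood"],
        particle=MATERIALS["gold"],
        phi=0.04,
        shape=SHAPES["platelet"],
    )


@pytest.fixture
def pure_blood_mix():
    return NanofluidMixture(
        base=MATERIALS["blood"],
        particle=MATERIALS["gold"],
        phi=0.0,
        shape=SHAPES["platelet"],
    )


@pytest.fixture
def default_params():
    return TherapyParams()


@pytest.fixture
def durbin_settings():
    return InversionSettings(method="durbin")


@pytest.fixture
def zakian_settings():
    return InversionSettings(method="zakian")


@pytest.fixture
def y21():
    return np.linspace(0.0, 1.0, 21)
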