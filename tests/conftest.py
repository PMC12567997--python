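import numpy as np
import pytest

from ringppg.finger import (
    FingerModel,
    FingerRegion,
    OpticalProperties,
    build_default_finger,
)


@pytest.fixture(scope="session")
def default_model():
    return build_default_finger((550, 628, 940))


def homogeneous_rod(mu_a, mu_s=0.0, g=0.0, n=1.0, label="microcirculation"):
    """Single-region cylinder filling the whole 19.2 mm finger cross-section."""
    props = {550: OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n)}
    region = FingerRegion(label, props, r_inner=0.0, r_outer=9.6)
    return FingerModel(
        regions=(region,), outer_radius=9.6, axial_length=20.0, wavelengths=(550,)
    )


@pytest.fixture(scope="session")
def scattering_rod():
    """All-microcirculation scattering phantom: any detected photon crossed it."""
    return homogeneous_rod(mu_a=0.05, mu_s=2.0, g=0.8, n=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
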