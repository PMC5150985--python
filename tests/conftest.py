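import numpy as np
import pytest

from striderjump import FluidProperties, InsectMorphology, StrokeModel


@pytest.fixture(scope="session")
def water() -> FluidProperties:
    return FluidProperties(density=998.0, surface_tension=0.072,
                           viscosity=1.0e-3, gravity=9.8)


@pytest.fixture(scope="session")
def exemplar_morphology() -> InsectMorphology:
    """Medium-sized strider exemplar: 30 mg body, 7.5 mm tibia+tarsus."""
    return InsectMorphology(
        body_mass=30e-6,
        leg_length=15e-3,
        support_length=7.5e-3,
        leg_radius=50e-6,
        rest_height=6.45e-3,
        name="medium_exemplar",
    )


@pytest.fixture
def stroke_model() -> StrokeModel:
    return StrokeModel(omega=50.0, max_reach=12e-3, rest_height=6e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160707)
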