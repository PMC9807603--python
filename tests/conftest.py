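import numpy as np
import pytest

from blastoseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def expansion_spec():
    return PhantomSpec(image_size=128, stage="expansion", embryo_radius=40,
                       zp_thickness=6, te_thickness=10, icm_radius=13, seed=3)


@pytest.fixture(scope="session")
def expansion_phantom(expansion_spec):
    return generate_phantom(expansion_spec)


@pytest.fixture(scope="session")
def hatched_phantom():
    spec = PhantomSpec(image_size=128, stage="hatched", embryo_radius=22,
                       zp_thickness=6, te_thickness=7, icm_radius=9,
                       hatch_gap_angle=100, hatched_fraction=0.7, seed=5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
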