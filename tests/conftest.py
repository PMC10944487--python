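import numpy as np
import pytest

from eetkit.lineshapes import LineshapeParams, SpectralModel
from eetkit.structure_io import PigmentSet, PigmentType
from eetkit.synthetic import make_charge_set, make_pigment

CHL_A_PARAMS = LineshapeParams(omega0=14900.0, fwhm=240.0, stokes=160.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def chl_a_model():
    return SpectralModel(by_type={PigmentType.CHL_A: CHL_A_PARAMS})


@pytest.fixture
def two_point_charges():
    """4 D two-point dipole charge set with 0.8 Å separation."""
    return make_charge_set(4.0, 0.8)


def random_pigment(rng, pid, chain, *, box=40.0, separation=0.8):
    center = rng.uniform(-box, box, size=3)
    axis = rng.normal(size=3)
    return make_pigment(
        pid, center, axis, chain=chain, resnum=1, separation=separation
    )


@pytest.fixture
def random_pair_factory(rng):
    """Pairs of random pigments guaranteed at least 8 Å apart."""

    def factory():
        while True:
            a = random_pigment(rng, "A/1/CLA", "A")
            b = random_pigment(rng, "B/1/CLA", "B")
            if np.linalg.norm(a.center - b.center) > 8.0:
                return PigmentSet([a, b])

    return factory
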