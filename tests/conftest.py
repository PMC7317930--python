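import numpy as np
import pytest
from shapely.geometry import Polygon

from immunogold import Calibration, CompartmentClass, Klass, Layer, ProfileGeometry


@pytest.fixture(scope="session")
def cal() -> Calibration:
    return Calibration.load()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260901)


def square_profile(
    side_nm: float = 1000.0,
    profile_id: str = "sq",
    face: str = "P",
    origin=(0.0, 0.0),
    **kwargs,
) -> ProfileGeometry:
    x0, y0 = origin
    poly = Polygon(
        [(x0, y0), (x0 + side_nm, y0), (x0 + side_nm, y0 + side_nm), (x0, y0 + side_nm)]
    )
    kwargs.setdefault(
        "compartment", CompartmentClass(Layer.SLM, Klass.OBLIQUE_DENDRITE)
    )
    return ProfileGeometry(id=profile_id, polygon=poly, face=face, **kwargs)


@pytest.fixture()
def unit_square() -> ProfileGeometry:
    """1 um^2 square profile."""
    return square_profile()
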