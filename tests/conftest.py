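import numpy as np
import pytest

from crestcurve import resample_equidistant, template_curve
from crestcurve.synthetic import GroupParams, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def template_polyline():
    """A curved crest template dense enough for sub-micron resampling."""
    return template_curve(8.0, 3.0, 350.0, n_points=1901)


@pytest.fixture
def varied_curves():
    """Six distinct smooth crest shapes as 20-point semilandmark curves."""
    return [
        resample_equidistant(
            template_curve(8.0 - 0.6 * i, 2.0 + 0.5 * i, 345.0 + 3 * i, n_points=401)
        )
        for i in range(6)
    ]


@pytest.fixture
def tiny_design():
    """Two small groups with distinct bow amplitudes, no noise by default."""
    return StudyDesign(
        groups=[
            GroupParams(name="old", n=8, n_male=4, ap_amplitude_mm=8.0,
                        ml_amplitude_mm=2.0, length_mm=355.0),
            GroupParams(name="new", n=8, n_male=4, ap_amplitude_mm=4.0,
                        ml_amplitude_mm=5.0, length_mm=355.0),
        ],
        seed=123,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
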