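import numpy as np
import pytest

from aortaview.centerline import RotationAngles
from aortaview.synthetic import AortaTemplateSpec, make_question_mark


@pytest.fixture(scope="session")
def planar_qmark():
    """The '?' aorta template, exactly planar (x = 0), identity embedding."""
    return make_question_mark(AortaTemplateSpec(embed_angles=(0.0, 0.0, 0.0)))


@pytest.fixture(scope="session")
def embedded_qmark():
    """Planar template embedded at known angles, with the angles."""
    angles = RotationAngles(0.7, 1.1, 2.0)
    c = make_question_mark(AortaTemplateSpec(embed_angles=angles))
    return c, angles


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
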