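import numpy as np
import pytest

from fepkit.landscape import MechanismStep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mechanism_steps():
    """The four-step urethanase mechanism: conformational activation,
    acylation (quoted from the global resting state), hydrolysis of the
    acyl-enzyme, and decarboxylation of carbamic acid."""
    return [
        MechanismStep("conformational", 4.5, 2.6),
        MechanismStep("acylation", 21.2, -16.7, "global_reference"),
        MechanismStep("hydrolysis", 18.2, -11.1),
        MechanismStep("decarboxylation", 12.1, 9.1),
    ]


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
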