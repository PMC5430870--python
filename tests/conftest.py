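import numpy as np
import pytest

import gliosim as g


@pytest.fixture(scope="session")
def small_spec():
    return g.default_spec(shape=(24, 24, 24), with_cavity=True, seed=3)


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return g.make_brain_phantom(small_spec)


@pytest.fixture(scope="session")
def small_dti(small_volume, small_spec):
    return g.make_tensor_field(small_volume, small_spec)


@pytest.fixture(scope="session")
def tissue_params():
    return g.TissueParams()


@pytest.fixture(scope="session")
def small_dbar(small_dti, small_volume, tissue_params):
    return g.build_growth_tensor(small_dti, small_volume, tissue_params)


def uniform_volume(label, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    """A volume of a single tissue class (no geometry invariants enforced)."""
    return g.LabeledVolume(np.full(shape, label, dtype=np.int16), spacing)
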