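import numpy as np
import pytest

from eegadapt.montage import azimuthal_project, packaged_montage


@pytest.fixture(scope="session")
def montage61():
    """Packaged 62-channel layout minus the Fz reference, projected."""
    return azimuthal_project(packaged_montage())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
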