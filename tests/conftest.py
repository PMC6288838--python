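import numpy as np
import pytest

from lineagequant.geometry import EmbryoGeometry
from lineagequant.optics import OpticsModel


@pytest.fixture(scope="session")
def optics():
    """Default vignetted, noisy imaging model."""
    return OpticsModel.default()


@pytest.fixture(scope="session")
def flat_optics():
    return OpticsModel.default(vignette=0.0)


@pytest.fixture(scope="session")
def trace_optics():
    """Flat, autofluorescence-free optics for time-lapse trace work."""
    return OpticsModel.default(vignette=0.0, autofluorescence_nM_equiv=0.0)


@pytest.fixture(scope="session")
def two_cell():
    return EmbryoGeometry.two_cell()


@pytest.fixture(scope="session")
def blank_embryo():
    return EmbryoGeometry.blank()


@pytest.fixture(scope="session")
def mask_cache():
    """Shared stage-mask cache to keep repeated lineage simulations cheap."""
    return {}
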