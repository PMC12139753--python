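import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fclsim.config import SimConfig
from fclsim.model_core import (
    BoxGeometry,
    KineticParams,
    SiteGeometryParams,
)
from fclsim.simulator import SimState


@pytest.fixture
def geom():
    return SiteGeometryParams()


@pytest.fixture
def box():
    return BoxGeometry(edge_nm=1000.0)


@pytest.fixture
def quiet_kin():
    """Kinetics with all rates zero (pure-diffusion states)."""
    return KineticParams(
        k_clat_clat_on_uM_s=0.0,
        k_clat_clat_off_s=0.0,
        k_clat_ap2_on_uM_s=0.0,
        k_clat_ap2_off_s=0.0,
    )


from helpers import make_state  # noqa: E402


@pytest.fixture
def state_factory():
    return make_state


@pytest.fixture
def desk_config():
    from fclsim.protocols import desk_preset

    return desk_preset()


@pytest.fixture
def tiny_config():
    return SimConfig(
        box_edge_um=0.5,
        n_clathrin=5,
        n_ap2=4,
        duration_s=0.01,
        frame_interval_s=0.005,
    ).with_overrides(**{"kinetics.dt_s": 1e-4})
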