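import numpy as np
import pytest

from omgrowth.flowfield import CylinderGeom, FlowSource, Patch, regular_polygon
from omgrowth.kinetics import KineticParams
from omgrowth.optics import NoiseModel, OpticsConfig
from omgrowth.simulator import init_state

# the headline kinetic triple: k_on (µm⁻² s⁻¹), k_ins (µm² s⁻¹), τ (s)
HEADLINE = dict(k_on=0.004, k_ins=0.00064, tau=50.0)
T_DOUBLE = 5400.0  # s


@pytest.fixture
def headline_params():
    return KineticParams(**HEADLINE)


@pytest.fixture
def geom():
    """Default cell: R = 0.5 µm, cylindrical length 2 µm."""
    return CylinderGeom(0.5, -1.0, 1.0)


@pytest.fixture
def quiet_optics():
    """Optics with negligible-noise camera for deterministic image tests."""
    return OpticsConfig(noise=NoiseModel(photon_scale=5e4, read_noise=2.0, offset=100.0))


def make_source(x, y, Q, duration=1e9, t_start=0.0, source_id=0, label="light"):
    return FlowSource(
        position=np.array([x, y], dtype=float),
        strength=Q,
        t_start=t_start,
        duration=duration,
        label=label,
        source_id=source_id,
    )


def state_with_patches(params, centers, area=1e-3, label="light", seed=0, geom=None):
    """A source-free state holding small regular polygons at given strip points."""
    st = init_state(geom, params, seed)
    for i, c in enumerate(centers):
        st.patches.append(
            Patch(
                vertices=regular_polygon(np.asarray(c, float), area, 12),
                label=label,
                source_id=1000 + i,
            )
        )
    return st
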