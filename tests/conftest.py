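import numpy as np
import pytest

from ctcscope import (
    CHANNELS,
    CameraSpec,
    OpticsGeometry,
    SimulationConfig,
    SnapSet,
    make_scene,
    render_snap,
)


@pytest.fixture(scope="session")
def paper_camera() -> CameraSpec:
    return CameraSpec()


@pytest.fixture(scope="session")
def paper_optics() -> OpticsGeometry:
    return OpticsGeometry()


@pytest.fixture(scope="session")
def small_optics() -> OpticsGeometry:
    """Quarter-FOV geometry at the instrument's pixel pitch, for speed."""
    return OpticsGeometry(fov_um=(153.0, 102.0), resolution_px=(256, 170))


def render_snapset(
    scene, config: SimulationConfig, snap_id: str = "snap", z: float = 0.0
) -> SnapSet:
    """Render all four channels of a scene into one SnapSet."""
    return SnapSet(
        images={ch: render_snap(scene, ch, z, config) for ch in CHANNELS},
        exposure_s=dict(config.exposure_s),
        snap_id=snap_id,
    )


@pytest.fixture
def small_scene(small_optics):
    """Well-separated mixed-phenotype scene on the quarter FOV."""
    return make_scene(3, 20, 15, extent_um=small_optics.fov_um, seed=11, min_sep_um=16)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
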