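"""Shared fixtures: geometries, small phantoms, and analytic projections."""

from __future__ import annotations

import numpy as np
import pytest

from detrack.geometry import build_geometry
from detrack.phantom import (
    AIR,
    LUNG,
    SOFT,
    ThoraxConfig,
    VoxelPhantom,
    make_thorax,
    make_tumor,
)


@pytest.fixture(scope="session")
def geom():
    """Full-resolution imaging geometry (512 x 512, 0.4 mm pitch)."""
    return build_geometry()


@pytest.fixture(scope="session")
def geom_small():
    """Coarse detector sampling of the same panel (64 x 64, 3.2 mm)."""
    return build_geometry(pixel_pitch=3.2, detector_shape=(64, 64))


@pytest.fixture(scope="session")
def thorax():
    return make_thorax()


@pytest.fixture(scope="session")
def thorax_config():
    return ThoraxConfig()


@pytest.fixture(scope="session")
def tumor_26():
    return make_tumor(26.0, 140.0, 35.0, shape_seed=260, spacing=1.0)


def make_slab_phantom(
    thickness_mm: float = 50.0,
    material: int = SOFT,
    lateral_mm: float = 400.0,
    si_mm: float = 400.0,
    spacing=(2.0, 2.0, 2.0),
) -> VoxelPhantom:
    """A uniform slab of one material, normal to the AP axis, centered on
    the isocenter — Beer-Lambert closed forms apply along the AP axis."""
    spacing = np.asarray(spacing, dtype=float)
    shape = (
        int(round(lateral_mm / spacing[0])),
        int(round(thickness_mm / spacing[1])),
        int(round(si_mm / spacing[2])),
    )
    labels = np.full(shape, material, dtype=np.uint8)
    hu = np.zeros(shape)
    origin = -(np.asarray(shape) - 1) / 2.0 * spacing
    return VoxelPhantom(labels=labels, hu=hu, spacing=spacing, origin=origin)


def make_air_phantom(**kw) -> VoxelPhantom:
    return make_slab_phantom(material=AIR, **kw)


@pytest.fixture()
def slab50():
    return make_slab_phantom(50.0)
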