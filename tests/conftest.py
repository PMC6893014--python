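"""Shared fixtures: default instrument models and small rendered scenes.

Scene sizes here are deliberately smaller than the full reference field
(256x256x41) so the suite stays fast; the acceptance test runs the full
geometry.
"""

import numpy as np
import pytest

from telo3d.models import CameraModel, NucleusSpec, OpticsModel, VoxelSpacing
from telo3d import synthetic_nuclei as sn

SMALL_SHAPE = (41, 160, 160)
SMALL_SEMI_AXES = (6.5, 4.5, 1.2)


@pytest.fixture(scope="session")
def optics() -> OpticsModel:
    return OpticsModel()


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def quiet_camera() -> CameraModel:
    """Camera without vignetting, for flux-accounting tests."""
    return CameraModel(vignetting_strength=0.0)


@pytest.fixture(scope="session")
def spacing() -> VoxelSpacing:
    return VoxelSpacing()


@pytest.fixture(scope="session")
def small_spec() -> NucleusSpec:
    """A full diploid complement in a reduced field."""
    return NucleusSpec(min_separation=1.0, nucleus_semi_axes=SMALL_SEMI_AXES)


@pytest.fixture(scope="session")
def noise_free_scene(small_spec, optics, quiet_camera, spacing):
    """One noise-free nucleus: analog channels plus ground truth."""
    return sn.simulate_nucleus(small_spec, optics, quiet_camera, spacing,
                               seed=123, shape=SMALL_SHAPE, noise=False,
                               vignetting=False)


@pytest.fixture(scope="session")
def noisy_scene(small_spec, optics, camera, spacing):
    """One default-noise nucleus at the reduced field size."""
    return sn.simulate_nucleus(small_spec, optics, camera, spacing,
                               seed=123, shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def calibration_frames(camera, spacing):
    darks, flat = sn.simulate_calibration_frames(
        camera, 15, SMALL_SHAPE[1:], seed=3, spacing=spacing)
    return darks, flat


def render_points(positions_um, fluxes, optics, spacing, shape=SMALL_SHAPE,
                  offset=0.0):
    """Expected-photon render of point emitters plus a constant offset."""
    img = sn.render_emitters(shape, np.asarray(positions_um, float),
                             np.asarray(fluxes, float), optics, spacing)
    return img + offset
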