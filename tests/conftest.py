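"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gland3d import DEFAULT_SPACING_UM, PhantomSpec, Tube
from gland3d.phantom import rasterize_ball, rasterize_tube

SPACING = DEFAULT_SPACING_UM


def brute_force_distance(vessel_mask: np.ndarray, spacing_um) -> np.ndarray:
    """All-pairs nearest-vessel-voxel distance field — the slow oracle.

    For every voxel centre, the minimum Euclidean distance (physical
    units) to any vessel voxel centre, computed by explicit enumeration.
    """
    sp = np.asarray(spacing_um, float)
    vox = np.argwhere(vessel_mask) * sp
    shape = vessel_mask.shape
    all_coords = np.indices(shape).reshape(3, -1).T * sp
    out = np.empty(len(all_coords))
    chunk = 4096
    for start in range(0, len(all_coords), chunk):
        block = all_coords[start:start + chunk]
        d2 = ((block[:, None, :] - vox[None, :, :]) ** 2).sum(axis=2)
        out[start:start + chunk] = np.sqrt(d2.min(axis=1))
    return out.reshape(shape)


def make_cylinder_mask(shape, spacing_um, p0_um, p1_um, radius_um) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rasterize_tube(mask, Tube(tuple(p0_um), tuple(p1_um), radius_um), spacing_um)
    return mask


def make_ball_mask(shape, spacing_um, center_um, radius_um) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rasterize_ball(mask, center_um, radius_um, spacing_um)
    return mask


@pytest.fixture(scope="session")
def spacing():
    return SPACING


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Noiseless single-cylinder phantom: r = 5 μm, analytic truth known."""
    from gland3d import generate_phantom

    spec = PhantomSpec(
        shape=(40, 60, 60),
        vessels=[Tube((16.4, 20.0, 5.0), (16.4, 20.0, 36.0), 5.0)],
        seed=1,
    )
    return generate_phantom(spec)
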