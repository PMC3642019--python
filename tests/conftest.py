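"""Shared fixtures: small analytic phantoms and noise-free projection sets."""

import numpy as np
import pytest

from vesselct import (
    FlatFieldModel,
    VesselSegment,
    VesselTree,
    project,
)


@pytest.fixture
def cylinder_tree():
    """A single vertical tube: radius 180 um (20 px), mu = 1e-3 / um."""
    return VesselTree(
        [VesselSegment([0, 0, 0], [0, 0, 900], 180.0, 0)],
        contrast_per_um=1e-3,
    )


def make_tube_tree(radius_um, x_um=0.0, y_um=0.0, height_um=900.0,
                   contrast=1e-3):
    return VesselTree(
        [VesselSegment([x_um, y_um, 0], [x_um, y_um, height_um], radius_um, 0)],
        contrast_per_um=contrast,
    )


def project_clean(tree, n_cols, angles=None, n_rows=3, **kwargs):
    """Noise-free unit-flat-field projections of a tree (rows centred on z)."""
    if angles is None:
        angles = np.arange(180.0)
    lo, hi = tree.bounding_box()
    z_mid = 0.5 * (lo[2] + hi[2])
    kwargs.setdefault("flat", np.ones((n_rows, n_cols)))
    return project(
        tree, angles_deg=angles,
        detector_shape=(n_rows, n_cols),
        z0_um=z_mid - (n_rows - 1) / 2 * 9.0,
        **kwargs,
    )


@pytest.fixture
def cylinder_projections(cylinder_tree):
    """180 noiseless projections of the centred cylinder on 128 columns."""
    return project_clean(cylinder_tree, 128)


def disk_truth(n, radius_px, cx_px=0.0, cy_px=0.0, value=1.0):
    """Per-pixel attenuation map of a disk, centre offsets in pixels."""
    c = (n - 1) / 2
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - c - cy_px, xx - c - cx_px)
    return np.where(r <= radius_px, value, 0.0)
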