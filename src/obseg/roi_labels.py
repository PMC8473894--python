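"""ROI training label construction and left/right splitting.

The localization stage is trained to segment a ball-shaped forebrain region
centred on the mid-point between the two olfactory bulbs.  The label is built
by placing an isotropic Gaussian at the OB centroid on the 1.6 mm grid and
thresholding its value relative to the analytic maximum at the mean: voxel x
is foreground iff

    exp(-||x - C||^2 / (2 sigma^2)) >= cutoff
    <=>  ||x - C|| <= sigma * sqrt(2 ln(1/cutoff))

so the region is a closed-form digital ball (radius ~6.68 voxels for the
defaults sigma=10, cutoff=0.8).  Distances are measured in voxel units of the
grid the label lives on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError, ParameterError
from .image_io import LabelMap


@dataclass(frozen=True)
class RoiSpec:
    """Gaussian spread (voxels) and relative cutoff of the ROI label."""

    sigma: float = 10.0
    cutoff: float = 0.8

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if not 0.0 < self.cutoff < 1.0:
            raise ParameterError("cutoff must lie in (0, 1)")

    @property
    def radius_voxels(self) -> float:
        return self.sigma * math.sqrt(2.0 * math.log(1.0 / self.cutoff))


@dataclass(frozen=True)
class Centroid:
    """Continuous 0-based voxel coordinates on a reference grid."""

    coords: tuple
    grid_shape: tuple


def compute_centroid(lab: LabelMap, foreground=(1, 2)) -> Centroid:
    """Arithmetic mean of the foreground voxel indices."""
    mask = np.isin(lab.data, list(foreground))
    if not mask.any():
        raise EmptyStructureError("no foreground voxels for centroid")
    coords = np.argwhere(mask).mean(axis=0)
    return Centroid(coords=tuple(float(c) for c in coords), grid_shape=lab.data.shape)


def make_roi_label(c: Centroid, grid_shape, spec: RoiSpec = RoiSpec(),
                   affine=None) -> LabelMap:
    """Binary ball label around the centroid (see module docstring)."""
    grid_shape = tuple(int(s) for s in grid_shape)
    coords = np.asarray(c.coords, dtype=np.float64)
    if np.any(coords < 0) or np.any(coords > np.array(grid_shape) - 1):
        raise ParameterError(f"centroid {c.coords} outside grid {grid_shape}")
    r2 = spec.radius_voxels ** 2
    gx, gy, gz = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    d2 = (gx - coords[0]) ** 2 + (gy - coords[1]) ** 2 + (gz - coords[2]) ** 2
    mask = d2 <= r2
    if not mask.any():
        raise EmptyStructureError("ROI cutoff leaves no foreground on this grid")
    if affine is None:
        affine = np.eye(4)
    return LabelMap(data=mask.astype(np.int16), affine=affine, codes=(0, 1))


def split_left_right(binary_ob: LabelMap) -> LabelMap:
    """Assign codes {1: left, 2: right} by the mid-sagittal plane through
    the mask centroid.

    Left/right is decided in world space: a voxel whose world x coordinate
    (RAS+, +x = subject's right) falls below the plane through the overall
    centroid is labelled left (1), otherwise right (2).  An empty input is a
    valid no-OB result and yields an empty output.
    """
    out = np.zeros_like(binary_ob.data, dtype=np.int16)
    fg = np.argwhere(binary_ob.data > 0)
    if fg.size == 0:
        return LabelMap(data=out, affine=binary_ob.affine, codes=(0, 1, 2))
    world_x = fg @ binary_ob.affine[0, :3] + binary_ob.affine[0, 3]
    plane = world_x.mean()
    left = world_x < plane
    out[tuple(fg[left].T)] = 1
    out[tuple(fg[~left].T)] = 2
    return LabelMap(data=out, affine=binary_ob.affine, codes=(0, 1, 2))
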