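"""NIfTI volume handling: reading, writing, conforming, cropping, slicing.

All internal processing happens on canonically oriented (RAS+) isotropic
grids.  Two working resolutions are used by the pipeline: 0.8 mm for tissue
segmentation and 1.6 mm for the coarse localization stage.  Conforming a
volume reorients it to RAS+, resamples it to the requested isotropic spacing
(trilinear for intensities, nearest-neighbour for label maps) and, for
intensity images, rescales it robustly to [0, 1].

Cropping keeps full geometric provenance (:class:`CropRecord`) so that a
label map produced inside a crop can be placed back at the exact source
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError, LocalizationError, ParameterError, ShapeError

#: slice plane -> axis normal to it, on a RAS+ canonical grid
PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
PLANES = ("axial", "coronal", "sagittal")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=np.float64)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("degenerate affine (zero determinant)")
    return affine


@dataclass
class VolumeImage:
    """A 3D scalar image with its voxel-to-world map (mm, RAS+ convention)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float32)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def orientation(self) -> str:
        return "".join(nib.aff2axcodes(self.affine))


@dataclass
class LabelMap:
    """Integer segmentation sharing a :class:`VolumeImage` grid.

    ``codes`` declares the allowed label values; the pipeline uses
    {0: background, 1: left OB, 2: right OB} or binary {0, 1}.
    """

    data: np.ndarray
    affine: np.ndarray
    codes: tuple = (0, 1, 2)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D label map, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int16)
        self.affine = _check_affine(self.affine)
        present = np.unique(self.data)
        if not set(present.tolist()) <= set(self.codes):
            raise ShapeError(f"label values {present} outside declared codes {self.codes}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class CropRecord:
    """Provenance of a fixed-size crop: source offset and applied padding.

    ``offset`` is the (possibly negative) source index of crop voxel (0,0,0);
    ``pad_before``/``pad_after`` are the zero-filled margins per axis.
    """

    offset: tuple
    size: tuple
    pad_before: tuple
    pad_after: tuple
    source_shape: tuple


@dataclass
class MultiSliceStack:
    """Per-view stacks of 3 consecutive slices (edge-replicated at faces).

    ``slabs`` has shape (n_slices, 3, H, W); channel *i* of slab *m* holds
    source slice ``m - 1 + i`` along the plane's normal axis.
    """

    plane: str
    slabs: np.ndarray
    index_of_middle: np.ndarray

    def __post_init__(self):
        if self.plane not in PLANE_AXES:
            raise ParameterError(f"unknown plane {self.plane!r}")
        if self.slabs.ndim != 4 or self.slabs.shape[1] != 3:
            raise ShapeError(f"slabs must be (n, 3, H, W), got {self.slabs.shape}")


def default_affine(voxel_mm: float | tuple, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Axis-aligned RAS+ affine with the given isotropic/anisotropic spacing."""
    v = np.broadcast_to(np.asarray(voxel_mm, dtype=np.float64), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(v)
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> VolumeImage:
    """Read a (optionally gzipped) NIfTI file as a floating-point volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ShapeError(f"{path.name}: expected a 3D image, got {img.ndim}D")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return VolumeImage(data=data, affine=img.affine)


def read_label(path, codes=(0, 1, 2)) -> LabelMap:
    v = read_volume(path)
    return LabelMap(data=np.rint(v.data).astype(np.int16), affine=v.affine, codes=codes)


def write_volume(v: VolumeImage | LabelMap, path) -> None:
    """Write to NIfTI; label maps get an integer on-disk dtype."""
    path = Path(path)
    if isinstance(v, LabelMap):
        data = v.data.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_data_dtype(data.dtype)
    img.to_filename(str(path))


def _to_ras(data: np.ndarray, affine: np.ndarray):
    """Reorder/flip axes so voxel axes point along +R, +A, +S."""
    ornt = nib.orientations.io_orientation(affine)
    ras = nib.orientations.ornt_transform(ornt, np.array([[0, 1.0], [1, 1.0], [2, 1.0]]))
    data2 = nib.orientations.apply_orientation(data, ras)
    affine2 = affine @ nib.orientations.inv_ornt_aff(ras, data.shape)
    return np.ascontiguousarray(data2), affine2


def robust_rescale(data: np.ndarray, plow=0.1, phigh=99.9) -> np.ndarray:
    """Percentile min-max normalization to [0, 1] with clipping.

    Order statistics are taken inclusively ('lower'/'higher' interpolation)
    so that rescaling an already-rescaled volume is an exact no-op: the mass
    clipped to 0 and 1 by the first pass then reproduces lo=0, hi=1.
    """
    lo = np.percentile(data, plow, method="lower")
    hi = np.percentile(data, phigh, method="higher")
    if hi <= lo:
        return np.zeros_like(data, dtype=np.float32)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def conform(v: VolumeImage | LabelMap, target_mm: float, mode: str = "intensity"):
    """Resample onto a canonical axis-aligned RAS+ grid at ``target_mm``.

    Intensity mode interpolates trilinearly and rescales robustly to [0, 1];
    label mode uses nearest-neighbour sampling and no rescaling.  The world
    extent of the volume is preserved within one voxel (output dimensions are
    ceil(n * vox / target)) and the world position of the volume centre is
    kept fixed.
    """
    if target_mm <= 0:
        raise ParameterError("target_mm must be positive")
    if mode not in ("intensity", "label"):
        raise ParameterError(f"unknown conform mode {mode!r}")

    data = np.asarray(v.data)
    if mode == "intensity":
        data = np.nan_to_num(data.astype(np.float32), copy=False)
    data, affine = _to_ras(data, v.affine)

    vox = np.linalg.norm(affine[:3, :3], axis=0)
    in_shape = np.array(data.shape)
    out_shape = np.ceil(in_shape * vox / target_mm - 1e-6).astype(int)
    out_shape = np.maximum(out_shape, 1)

    center_world = affine @ np.append((in_shape - 1) / 2.0, 1.0)
    out_affine = np.eye(4)
    out_affine[:3, :3] = np.eye(3) * target_mm
    out_affine[:3, 3] = center_world[:3] - target_mm * (out_shape - 1) / 2.0

    M = np.linalg.inv(affine) @ out_affine
    order = 1 if mode == "intensity" else 0
    src = data if mode == "intensity" else data.astype(np.int16)
    out = ndimage.affine_transform(
        src, M[:3, :3], offset=M[:3, 3], output_shape=tuple(out_shape),
        order=order, mode="constant", cval=0, prefilter=False,
    )
    if mode == "intensity":
        return VolumeImage(data=robust_rescale(out), affine=out_affine)
    codes = v.codes if isinstance(v, LabelMap) else (0, 1, 2)
    return LabelMap(data=out.astype(np.int16), affine=out_affine, codes=codes)


def _crop_affine(affine: np.ndarray, offset) -> np.ndarray:
    shift = np.eye(4)
    shift[:3, 3] = offset
    return affine @ shift


def crop_with_padding(v: VolumeImage, center, size=(96, 96, 96)):
    """Extract a fixed-size crop centred at a voxel, zero-padding out-of-bounds.

    Returns ``(cropped VolumeImage, CropRecord)``.  ``center`` must lie inside
    the source grid; a violation signals a failed localization stage.
    """
    center = np.asarray(np.rint(center), dtype=int)
    size = tuple(int(s) for s in size)
    shape = np.array(v.data.shape)
    if np.any(center < 0) or np.any(center >= shape):
        raise LocalizationError(f"crop center {tuple(center)} outside grid {tuple(shape)}")
    offset = center - np.array(size) // 2
    start = np.maximum(offset, 0)
    end = np.minimum(offset + size, shape)
    pad_before = np.maximum(-offset, 0)
    pad_after = np.maximum(offset + size - shape, 0)
    out = np.zeros(size, dtype=v.data.dtype)
    out[
        pad_before[0]:size[0] - pad_after[0],
        pad_before[1]:size[1] - pad_after[1],
        pad_before[2]:size[2] - pad_after[2],
    ] = v.data[start[0]:end[0], start[1]:end[1], start[2]:end[2]]
    rec = CropRecord(
        offset=tuple(int(o) for o in offset),
        size=size,
        pad_before=tuple(int(p) for p in pad_before),
        pad_after=tuple(int(p) for p in pad_after),
        source_shape=tuple(int(s) for s in shape),
    )
    return VolumeImage(data=out, affine=_crop_affine(v.affine, offset)), rec


def uncrop(lab: LabelMap, rec: CropRecord, source_affine: np.ndarray) -> LabelMap:
    """Place a cropped label map back onto the source grid (background outside)."""
    if tuple(lab.data.shape) != tuple(rec.size):
        raise GeometryError(f"label shape {lab.data.shape} != crop size {rec.size}")
    out = np.zeros(rec.source_shape, dtype=lab.data.dtype)
    offset = np.array(rec.offset)
    size = np.array(rec.size)
    pb = np.array(rec.pad_before)
    pa = np.array(rec.pad_after)
    start = np.maximum(offset, 0)
    end = np.minimum(offset + size, np.array(rec.source_shape))
    out[start[0]:end[0], start[1]:end[1], start[2]:end[2]] = lab.data[
        pb[0]:size[0] - pa[0], pb[1]:size[1] - pa[1], pb[2]:size[2] - pa[2]
    ]
    return LabelMap(data=out, affine=np.asarray(source_affine), codes=lab.codes)


def extract_multislice_stacks(v: VolumeImage, plane: str) -> MultiSliceStack:
    """Build 3-channel slice stacks along ``plane`` with edge replication.

    One slab is produced per source slice along the plane's normal axis; the
    middle channel is that slice, the outer channels its neighbours (the first
    and last slices replicate their own edge).
    """
    if plane not in PLANE_AXES:
        raise ParameterError(f"unknown plane {plane!r}")
    axis = PLANE_AXES[plane]
    vol = np.moveaxis(v.data, axis, 0)
    n = vol.shape[0]
    idx = np.arange(n)
    prev = np.clip(idx - 1, 0, n - 1)
    nxt = np.clip(idx + 1, 0, n - 1)
    slabs = np.stack([vol[prev], vol[idx], vol[nxt]], axis=1).astype(np.float32)
    return MultiSliceStack(plane=plane, slabs=slabs, index_of_middle=idx)


def reassemble_volume(prob_slabs: np.ndarray, plane: str) -> np.ndarray:
    """Stack per-slice class probabilities back into a (L, X, Y, Z) volume."""
    axis = PLANE_AXES[plane]
    # prob_slabs: (n_slices, L, H, W) -> (L, n, H, W) -> move n to `axis`
    vol = np.moveaxis(prob_slabs, 0, 1)
    return np.moveaxis(vol, 1, axis + 1)


def resample_labels_like(lab: LabelMap, target_affine: np.ndarray,
                         target_shape: tuple) -> LabelMap:
    """Nearest-neighbour resample of a label map onto another grid."""
    M = np.linalg.inv(lab.affine) @ np.asarray(target_affine)
    out = ndimage.affine_transform(
        lab.data.astype(np.int16), M[:3, :3], offset=M[:3, 3],
        output_shape=tuple(target_shape), order=0, mode="constant", cval=0,
        prefilter=False,
    )
    return LabelMap(data=out, affine=np.asarray(target_affine), codes=lab.codes)


def grids_match(a_affine, a_shape, b_affine, b_shape, tol=1e-3) -> bool:
    return tuple(a_shape) == tuple(b_shape) and np.allclose(a_affine, b_affine, atol=tol)
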