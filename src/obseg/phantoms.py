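"""Synthetic T2-like head phantoms with ground-truth olfactory bulb labels.

Each phantom is a head-sized ellipsoid of mid-grey tissue wrapped in a bright
rim (cerebrospinal fluid appears bright on T2-weighted contrast), with a
bright CSF pocket at the anterior-inferior base in which a mirrored pair of
small dark ellipsoids stands in for the olfactory bulbs — the appearance the
segmentation problem relies on: dark tissue demarcated by surrounding CSF.
Additive Gaussian noise and an optional smooth multiplicative bias field
emulate acquisition effects.  Phantoms are deterministic given their seed.

Cohorts programme a linear (negative) dependence of total OB volume on age so
that sensitivity analyses — does a segmentation method recover a known
volume-age slope? — can run on synthetic data.  Adult total OB volumes span
roughly 12-111 mm^3, which the generator respects via clipping.

OBs are placed adjacent to the inferior head boundary on purpose: crops
centred on them extend beyond the volume and exercise the zero-padding path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, SpecError
from .image_io import LabelMap, VolumeImage, default_affine


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry (mm, world coordinates centred on the grid), intensities and
    noise of one synthetic head."""

    grid_shape: tuple = (160, 160, 160)
    voxel_mm: float = 0.8
    head_semi_axes_mm: tuple = (45.0, 55.0, 45.0)
    head_center_mm: tuple = (0.0, 0.0, 6.0)
    rim_fraction: float = 0.93          # inner tissue ellipsoid, scaled
    tissue_intensity: float = 0.55
    csf_intensity: float = 0.95
    background_intensity: float = 0.05
    ob_intensity: float = 0.25
    ob_centers_mm: tuple = ((-4.0, 20.0, -34.0), (4.0, 20.0, -34.0))
    ob_semi_axes_mm: tuple = ((1.5, 3.1, 1.4), (1.5, 3.1, 1.4))
    pocket_margin_mm: float = 2.5
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.1
    present: tuple = (True, True)
    seed: int = 0

    def __post_init__(self):
        left, right = self.ob_centers_mm
        if not left[0] < right[0]:
            raise SpecError("left OB centre must have the smaller x coordinate")
        for semi in self.ob_semi_axes_mm:
            vol = self.side_volume_mm3(semi)
            if not 6.0 <= vol <= 60.0:
                raise SpecError(f"per-side OB volume {vol:.1f} mm^3 outside [6, 60]")
        for center, semi in zip(self.ob_centers_mm, self.ob_semi_axes_mm):
            c = np.asarray(center) - np.asarray(self.head_center_mm)
            extent = (np.abs(c) + np.asarray(semi)) / np.asarray(self.head_semi_axes_mm)
            if np.sum(extent ** 2) > 3.0:  # generous triangle bound
                raise SpecError("OB ellipsoid lies outside the head")

    @staticmethod
    def side_volume_mm3(semi_axes) -> float:
        a, b, c = semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def true_volumes_mm3(self) -> tuple:
        vols = [self.side_volume_mm3(s) if p else 0.0
                for s, p in zip(self.ob_semi_axes_mm, self.present)]
        return tuple(vols)


def _ellipsoid_mask(coords, center, semi_axes) -> np.ndarray:
    d = [(coords[i] - center[i]) / semi_axes[i] for i in range(3)]
    return d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Rasterise one phantom; returns (VolumeImage, LabelMap {0,1,2})."""
    shape = tuple(int(s) for s in spec.grid_shape)
    extent = (np.array(shape) - 1) * spec.voxel_mm
    affine = default_affine(spec.voxel_mm, origin=-extent / 2.0)
    axes = [np.arange(n) * spec.voxel_mm - e / 2.0
            for n, e in zip(shape, extent)]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)

    img = np.full(shape, spec.background_intensity, dtype=np.float32)
    head = _ellipsoid_mask(coords, spec.head_center_mm, spec.head_semi_axes_mm)
    inner = _ellipsoid_mask(coords, spec.head_center_mm,
                            np.asarray(spec.head_semi_axes_mm) * spec.rim_fraction)
    img[head] = spec.csf_intensity
    img[inner] = spec.tissue_intensity

    lab = np.zeros(shape, dtype=np.int16)
    for side, (center, semi, present) in enumerate(
            zip(spec.ob_centers_mm, spec.ob_semi_axes_mm, spec.present)):
        pocket = _ellipsoid_mask(coords, center,
                                 np.asarray(semi) + spec.pocket_margin_mm)
        img[pocket & head] = spec.csf_intensity
        if present:
            ob = _ellipsoid_mask(coords, center, semi)
            img[ob] = spec.ob_intensity
            lab[ob] = side + 1  # 1 = left (smaller x), 2 = right

    rng = np.random.default_rng(spec.seed)
    if spec.bias_amplitude > 0:
        # low-order separable modulation, deterministic per seed
        phases = rng.uniform(0, 2 * math.pi, 3)
        freqs = rng.uniform(0.5, 1.5, 3)
        bias = np.ones(shape, dtype=np.float32)
        for ax in range(3):
            t = np.linspace(0, math.pi, shape[ax], dtype=np.float32)
            mod = 1.0 + spec.bias_amplitude / 3.0 * np.sin(freqs[ax] * t + phases[ax])
            shape_b = [1, 1, 1]
            shape_b[ax] = shape[ax]
            bias *= mod.reshape(shape_b)
        img = img * bias
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.5)

    return VolumeImage(img.astype(np.float32), affine), LabelMap(lab, affine)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort with a programmed linear age-volume model:
    total_volume(age) = beta0 + beta_age * age + N(0, sigma), clipped to a
    plausible adult range."""

    n: int = 12
    age_range: tuple = (30.0, 85.0)
    sex_ratio: float = 0.5
    beta0: float = 70.5
    beta_age: float = -0.3
    noise_sigma: float = 5.0
    clip_mm3: tuple = (12.0, 120.0)
    grid_shape: tuple = (160, 160, 160)
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("cohort needs n >= 2")
        if self.beta_age >= 0:
            raise SpecError("the programmed age slope must be negative")
        mean_mid = self.beta0 + self.beta_age * np.mean(self.age_range)
        if not self.clip_mm3[0] <= mean_mid <= self.clip_mm3[1]:
            raise SpecError("volume model infeasible: mid-age mean outside clip range")


def _spec_for_volume(total_mm3: float, grid_shape, seed: int,
                     asymmetry: float, present=(True, True)) -> PhantomSpec:
    """Scale the default geometry to a grid and distribute a total OB volume
    over two mirrored spindle-shaped ellipsoids."""
    base = PhantomSpec()
    scale = (np.asarray(grid_shape, float) * 0.8) / (np.asarray(base.grid_shape) * 0.8)
    head_semi = tuple(np.asarray(base.head_semi_axes_mm) * scale)
    head_center = tuple(np.asarray(base.head_center_mm) * scale)
    # keep the bulbs near the inferior-anterior head boundary after scaling:
    # place them at 88% of the normalised ellipsoid radius, pointing
    # anterior-inferior, at a fixed ~4 mm lateral offset from the midline
    ob_x = min(4.0, 0.35 * head_semi[0])
    rx = ob_x / head_semi[0]
    s = math.sqrt(max(0.88 ** 2 - rx ** 2, 0.0))
    dir_yz = np.array([0.45, -0.85])
    dir_yz = dir_yz / np.linalg.norm(dir_yz)
    ob_y = head_center[1] + s * dir_yz[0] * head_semi[1]
    ob_z = head_center[2] + s * dir_yz[1] * head_semi[2]
    sides = []
    fracs = (0.5 - asymmetry / 2.0, 0.5 + asymmetry / 2.0)
    for frac in fracs:
        v = np.clip(frac * total_mm3, 6.0, 60.0)
        # spindle: elongated along the anterior-posterior (y) axis
        t = (v / (4.0 / 3.0 * math.pi * 0.8 * 1.7 * 0.75)) ** (1.0 / 3.0)
        sides.append((0.8 * t, 1.7 * t, 0.75 * t))
    return replace(
        base,
        grid_shape=tuple(int(g) for g in grid_shape),
        head_semi_axes_mm=head_semi,
        head_center_mm=head_center,
        ob_centers_mm=((-ob_x, ob_y, ob_z), (ob_x, ob_y, ob_z)),
        ob_semi_axes_mm=(tuple(sides[0]), tuple(sides[1])),
        present=present,
        seed=seed,
    )


def generate_cohort(cs: CohortSpec):
    """Per-subject phantom specs plus a metadata table.

    Returns ``(specs, table)`` where the table holds id, age, sex and the
    analytic per-side volumes actually realised (after clipping).
    """
    rng = np.random.default_rng(cs.seed)
    ages = rng.uniform(*cs.age_range, cs.n)
    n_female = int(round(cs.n * cs.sex_ratio))
    sexes = np.array(["f"] * n_female + ["m"] * (cs.n - n_female))
    rng.shuffle(sexes)
    totals = cs.beta0 + cs.beta_age * ages + rng.normal(0, cs.noise_sigma, cs.n)
    totals = np.clip(totals, *cs.clip_mm3)
    specs, rows = [], []
    for i in range(cs.n):
        asym = rng.uniform(-0.08, 0.08)
        spec = _spec_for_volume(float(totals[i]), cs.grid_shape,
                                seed=int(rng.integers(2 ** 31)), asymmetry=asym)
        left, right = spec.true_volumes_mm3
        specs.append(spec)
        rows.append({"id": f"sub-{i:03d}", "age": float(ages[i]),
                     "sex": str(sexes[i]), "true_left_mm3": left,
                     "true_right_mm3": right, "true_total_mm3": left + right})
    return specs, pd.DataFrame(rows)


def generate_no_ob_set(n: int, seed: int = 0, grid_shape=(160, 160, 160)):
    """Phantoms whose ground-truth OB volume is exactly zero (absent bulbs)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        spec = _spec_for_volume(54.0, grid_shape, seed=int(rng.integers(2 ** 31)),
                                asymmetry=0.0, present=(False, False))
        specs.append(spec)
    return specs
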