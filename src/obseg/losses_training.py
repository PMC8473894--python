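"""Composed focal+dice loss, boundary weighting, augmentation and training.

The networks optimise, per slice,

    Loss = - sum_x w(x) (1 - p_{l(x)}(x))^gamma log p_{l(x)}(x)          (focal)
           - sum_l 2 sum_x p_l g_l / (sum_x p_l^2 + sum_x g_l^2)         (dice)

where p_l(x) is the predicted probability of class l at pixel x, g the
one-hot ground truth and gamma=2 the focusing exponent.  The pixel weights
w(x) combine median-frequency class balancing with a bonus on pixels adjacent
to a class boundary, which counteracts the extreme foreground/background
imbalance of a structure occupying ~1e-5 of a head volume.

Training runs per anatomical view with Adam, a step learning-rate decay
(x0.95 every 5 epochs), online spatial augmentation applied to the full
volume *before* cropping (so crops never contain interpolation padding) and
subject-level intensity augmentation (multiplicative bias field, blur).
Checkpoint selection maximises validation Dice on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

import yaml

from .errors import ParameterError
from .image_io import LabelMap, VolumeImage, extract_multislice_stacks, reassemble_volume
from .nn import Adam, Tensor
from .nn import autograd as ag
from .networks import (NetworkSpec, build_localization_net,
                       build_segmentation_net, forward_view)
from .roi_labels import compute_centroid

_EPS = 1e-7  # probability clamp for log stability


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def boundary_weight_map(lab_slice: np.ndarray, edge_weight: float | None = None
                        ) -> np.ndarray:
    """Median-frequency class weights plus an edge bonus along boundaries.

    Interior pixels of class l get median(all class frequencies)/freq(l);
    pixels whose 8-neighbourhood (including themselves) touches a different
    label additionally receive ``edge_weight`` (default: twice the largest
    class weight).  A single-class slice yields uniform weight 1.
    """
    lab = np.asarray(lab_slice)
    classes, counts = np.unique(lab, return_counts=True)
    freqs = counts / counts.sum()
    med = np.median(freqs)
    w = np.empty(lab.shape, dtype=np.float32)
    for c, f in zip(classes, freqs):
        w[lab == c] = med / f
    if len(classes) > 1:
        if edge_weight is None:
            edge_weight = 2.0 * float(med / freqs.min())
        edge = (ndimage.maximum_filter(lab, size=3) !=
                ndimage.minimum_filter(lab, size=3))
        w[edge] += edge_weight
    return w


def _class_dice_terms(p, g, sum_axes, eps: float):
    """Per-class soft dice 2*sum(pg)/(sum(p^2)+sum(g^2)) via autograd ops."""
    num = ag.tsum(p * g, axis=sum_axes) * 2.0
    den = ag.tsum(p * p, axis=sum_axes) + ag.tsum(g * g, axis=sum_axes)
    if eps:
        return (num + eps) / (den + eps)
    return num / den


def composed_loss(p, g, w=None, gamma: float = 2.0):
    """Weighted focal loss minus per-class soft dice for one slice.

    ``p`` and ``g`` have the class on axis 0 (g one-hot); ``w`` broadcasts
    over the spatial axes (default 1).  Lower is better; the minimum is
    ``-n_classes``, attained at a perfect prediction.  Accepts plain arrays
    (returns a float) or autograd tensors (returns a Tensor).
    """
    tensor_in = isinstance(p, Tensor)
    p_t = p if tensor_in else Tensor(np.asarray(p, dtype=np.float64))
    g_t = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=p_t.data.dtype))
    if np.any(p_t.data < 0) or np.any(p_t.data > 1):
        raise ParameterError("probabilities must lie in [0, 1]")
    if w is None:
        w_t = Tensor(np.ones((1,) * (p_t.ndim - 1), dtype=p_t.data.dtype))
    else:
        w_t = w if isinstance(w, Tensor) else Tensor(np.asarray(w, dtype=p_t.data.dtype))
    pc = ag.clip(p_t, _EPS, 1.0 - _EPS)
    focal = ag.tsum(w_t * (1.0 - pc) ** gamma * g_t * (-ag.log(pc)))
    spatial_axes = tuple(range(1, p_t.ndim))
    num = ag.tsum(p_t * g_t, axis=spatial_axes) * 2.0
    den = ag.tsum(p_t * p_t, axis=spatial_axes) + ag.tsum(g_t * g_t, axis=spatial_axes)
    dice_total = Tensor(0.0)
    for l in range(p_t.data.shape[0]):
        num_l = ag.reshape(num, (p_t.data.shape[0],))
        den_l = ag.reshape(den, (p_t.data.shape[0],))
        # a class absent from both maps contributes a perfect score
        if den.data.reshape(-1)[l] == 0:
            dice_total = dice_total + 1.0
        else:
            dice_total = dice_total + _slice_index(num_l, l) / _slice_index(den_l, l)
    loss = focal - dice_total
    return loss if tensor_in else float(loss.data)


def _slice_index(t: Tensor, i: int) -> Tensor:
    """Differentiable selection of element ``i`` from a 1-D tensor."""
    mask = np.zeros(t.data.shape, dtype=t.data.dtype)
    mask[i] = 1.0
    return ag.tsum(t * Tensor(mask))


def batch_composed_loss(p: Tensor, g: Tensor, w: Tensor, gamma: float = 2.0) -> Tensor:
    """Mean over a (B, L, H, W) batch of the per-slice composed loss.

    Vectorised training path; a small smoothing term in the dice denominator
    guards against all-background slices with vanishing class mass.
    """
    B = p.data.shape[0]
    pc = ag.clip(p, _EPS, 1.0 - _EPS)
    w4 = ag.reshape(w, (w.data.shape[0], 1, *w.data.shape[1:]))
    focal = ag.tsum(w4 * (1.0 - pc) ** gamma * g * (-ag.log(pc)))
    dice = ag.tsum(_class_dice_terms(p, g, (2, 3), eps=1e-6))
    return (focal - dice) * (1.0 / B)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes, *labels.shape[1:]), dtype=np.float32)
    for l in range(n_classes):
        out[:, l] = labels == l
    return out


# ---------------------------------------------------------------------------
# schedule / config
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimisation schedule; defaults match the full-scale training recipe.

    ``filters`` and ``crop_size`` exist so that desk-scale runs (small
    synthetic cohorts on a CPU) can shrink the networks and the localized
    volume without touching the training logic.
    """

    epochs: int = 40
    batch_size: int = 16
    lr0: float = 0.01
    weight_decay: float = 1e-4
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    lr_factor: float = 0.95
    lr_step_epochs: int = 5
    gamma: float = 2.0
    seed: int = 0
    filters: int = 64
    crop_size: int = 96
    augment: bool = True
    #: fraction of the slice pool sampled (without replacement) per epoch;
    #: < 1 is plain stochastic subsampling for desk-scale runs
    slice_fraction: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        known = {k: v for k, v in raw.items() if hasattr(cfg, k)}
        if "betas" in known:
            known["betas"] = tuple(known["betas"])
        return replace(cfg, **known)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: lr0 * factor^floor(epoch / step)."""
    if epoch < 0:
        raise ParameterError("epoch must be >= 0")
    return cfg.lr0 * cfg.lr_factor ** (epoch // cfg.lr_step_epochs)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    translation_mm: float = 8.0
    rotation_deg: float = 10.0
    scale_range: tuple = (0.9, 1.1)
    bias_amplitude: float = 0.3
    blur_sigma_max: float = 1.0
    probability: float = 0.5


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def draw_spatial_params(rng: np.random.Generator,
                        cfg: AugmentConfig = AugmentConfig()) -> dict:
    return {
        "translation_mm": rng.uniform(-cfg.translation_mm, cfg.translation_mm, 3),
        "rotation_deg": rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, 3),
        "scale": rng.uniform(*cfg.scale_range),
    }


def spatial_augment(vol: VolumeImage, lab: LabelMap, params: dict | None = None,
                    rng: np.random.Generator | None = None):
    """Apply one rigid+scaling transform to a paired image and label volume.

    The transform acts about the volume centre on the FULL volume (trilinear
    for intensities, nearest-neighbour for labels) so that subsequent crops
    contain no interpolation padding.  Returns (volume, labels, params).
    """
    if params is None:
        if rng is None:
            raise ParameterError("either params or rng must be given")
        params = draw_spatial_params(rng)
    t = np.asarray(params["translation_mm"], dtype=float)
    angles = np.asarray(params["rotation_deg"], dtype=float)
    s = float(params["scale"])
    if np.allclose(t, 0) and np.allclose(angles, 0) and s == 1.0:
        return (VolumeImage(vol.data.copy(), vol.affine),
                LabelMap(lab.data.copy(), lab.affine, lab.codes), params)
    vox = np.asarray(vol.voxel_size)
    c = (np.array(vol.data.shape) - 1) / 2.0
    R = _rotation_matrix(angles)
    matrix = R.T / s                       # output voxel -> input voxel
    offset = c - matrix @ (c + t / vox)
    img = ndimage.affine_transform(vol.data, matrix, offset=offset, order=1,
                                   mode="constant", cval=0.0, prefilter=False)
    seg = ndimage.affine_transform(lab.data, matrix, offset=offset, order=0,
                                   mode="constant", cval=0, prefilter=False)
    return (VolumeImage(img, vol.affine), LabelMap(seg, lab.affine, lab.codes),
            params)


def draw_intensity_params(rng: np.random.Generator,
                          cfg: AugmentConfig = AugmentConfig()) -> dict:
    params = {"bias": None, "blur_sigma": None}
    if rng.uniform() < cfg.probability:
        exponents = [(i, j, k) for i in range(4) for j in range(4) for k in range(4)
                     if 1 <= i + j + k <= 3]
        params["bias"] = {
            "coeffs": rng.normal(0.0, 1.0, len(exponents)),
            "exponents": exponents,
            "amplitude": rng.uniform(0.0, cfg.bias_amplitude),
        }
    if rng.uniform() < cfg.probability:
        params["blur_sigma"] = rng.uniform(0.0, cfg.blur_sigma_max)
    return params


def bias_field(shape, coeffs, exponents, amplitude) -> np.ndarray:
    """Smooth multiplicative polynomial field, 1 +/- amplitude at the extremes."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    f = np.zeros(shape, dtype=np.float64)
    for c, (i, j, k) in zip(coeffs, exponents):
        f += c * gx ** i * gy ** j * gz ** k
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak * amplitude
    return (1.0 + f).astype(np.float32)


def intensity_augment(vol: VolumeImage, rng: np.random.Generator | None = None,
                      params: dict | None = None,
                      cfg: AugmentConfig = AugmentConfig()):
    """Subject-level intensity transforms: bias field and Gaussian blur.

    Parameters are drawn once per volume and returned so the identical
    transform is shared by every slice/view of that subject.
    """
    if params is None:
        if rng is None:
            raise ParameterError("either params or rng must be given")
        params = draw_intensity_params(rng, cfg)
    data = vol.data
    if params["bias"] is not None:
        b = params["bias"]
        data = data * bias_field(data.shape, b["coeffs"], b["exponents"],
                                 b["amplitude"])
    if params["blur_sigma"] is not None and params["blur_sigma"] > 0:
        data = ndimage.gaussian_filter(data, params["blur_sigma"])
    return VolumeImage(np.asarray(data, np.float32), vol.affine), params


# ---------------------------------------------------------------------------
# stratified splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Assignment of subjects to k disjoint groups balanced per stratum."""

    k: int
    assignment: dict
    strata: dict

    def members(self, group: int) -> list:
        return [s for s, g in self.assignment.items() if g == group]


def make_stratified_splits(subjects: pd.DataFrame, k: int = 4, seed: int = 0,
                           n_age_bins: int = 2) -> SplitPlan:
    """Round-robin assignment within age-bin x sex strata after a seeded
    shuffle, spreading each stratum across groups as evenly as possible."""
    if len(subjects) == 0:
        raise ParameterError("empty subject table")
    if len(subjects) < k:
        raise ParameterError(f"need at least k={k} subjects")
    df = subjects.copy()
    ids = df["id"] if "id" in df.columns else df.index.to_series()
    try:
        age_bin = pd.qcut(df["age"], q=n_age_bins, labels=False, duplicates="drop")
    except ValueError:
        age_bin = pd.Series(0, index=df.index)
    age_bin = age_bin.fillna(0).astype(int)
    strata = df["sex"].astype(str) + "/" + age_bin.astype(str)
    rng = np.random.default_rng(seed)
    assignment, strata_map = {}, {}
    for stratum in sorted(strata.unique()):
        members = [ids.loc[i] for i in df.index[strata == stratum]]
        members = sorted(members, key=str)
        rng.shuffle(members)
        for pos, subject in enumerate(members):
            assignment[subject] = pos % k
            strata_map[subject] = stratum
    return SplitPlan(k=k, assignment=assignment, strata=strata_map)


# ---------------------------------------------------------------------------
# datasets and the per-view training loop
# ---------------------------------------------------------------------------

class SlicePairDataset:
    """Paired full volumes and label maps feeding per-view slice training.

    ``crop_size`` crops a cube centred on the label centroid after any
    augmentation (the segmentation stage); ``None`` keeps the full volume
    (the localization stage).  Labels are binarised (foreground = any
    nonzero code) because both stages segment a single combined structure.
    """

    def __init__(self, pairs: list, subject_ids: list | None = None,
                 crop_size: int | None = None,
                 augment: AugmentConfig | None = None):
        if not pairs:
            raise ParameterError("empty dataset")
        self.pairs = pairs
        self.subject_ids = subject_ids or list(range(len(pairs)))
        self.crop_size = crop_size
        self.augment = augment or AugmentConfig()

    def subset(self, ids) -> "SlicePairDataset":
        idx = [self.subject_ids.index(i) for i in ids]
        return SlicePairDataset([self.pairs[i] for i in idx], list(ids),
                                self.crop_size, self.augment)

    def realised_volumes(self, rng: np.random.Generator | None, augment: bool):
        """Yield (volume, binary labels) per subject, optionally augmented and
        cropped.  Crops are centred on the (augmented) ground-truth centroid;
        empty labels fall back to the volume centre."""
        from .image_io import crop_with_padding  # local import, avoids cycle

        for vol, lab in self.pairs:
            if augment:
                vol, lab, _ = spatial_augment(vol, lab, rng=rng)
                vol, _ = intensity_augment(vol, rng=rng, cfg=self.augment)
            if self.crop_size is not None:
                fg = np.argwhere(lab.data > 0)
                center = (fg.mean(axis=0) if fg.size else
                          (np.array(vol.data.shape) - 1) / 2.0)
                size = (self.crop_size,) * 3
                vol, rec = crop_with_padding(vol, center, size)
                lab_crop = np.zeros(size, dtype=np.int16)
                off = np.array(rec.offset)
                lo = np.maximum(off, 0)
                hi = np.minimum(off + size, lab.data.shape)
                pb = np.array(rec.pad_before)
                pa = np.array(rec.pad_after)
                lab_crop[pb[0]:size[0] - pa[0], pb[1]:size[1] - pa[1],
                         pb[2]:size[2] - pa[2]] = lab.data[lo[0]:hi[0],
                                                           lo[1]:hi[1], lo[2]:hi[2]]
                lab = LabelMap(lab_crop, vol.affine, lab.codes)
            yield vol, (lab.data > 0).astype(np.int16)

    def epoch_arrays(self, view: str, rng: np.random.Generator, augment: bool):
        """Stacked (X, Y, W) arrays of all slices of all subjects for a view."""
        xs, ys, ws = [], [], []
        for vol, binlab in self.realised_volumes(rng, augment):
            stacks = extract_multislice_stacks(vol, view)
            axis = {"sagittal": 0, "coronal": 1, "axial": 2}[view]
            labels = np.moveaxis(binlab, axis, 0)
            xs.append(stacks.slabs)
            ys.append(labels)
            ws.append(np.stack([boundary_weight_map(s) for s in labels]))
        return (np.concatenate(xs), np.concatenate(ys).astype(np.int16),
                np.concatenate(ws).astype(np.float32))


def predict_view_volume(net, vol: VolumeImage, view: str,
                        batch_size: int = 16) -> np.ndarray:
    """Per-voxel class probabilities for one volume through one view network."""
    stacks = extract_multislice_stacks(vol, view)
    probs = forward_view(net, stacks, batch_size=batch_size)
    return reassemble_volume(probs, view)


@dataclass
class TrainedModel:
    net: object
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float


def train_view_model(dataset: SlicePairDataset, view: str, spec: NetworkSpec,
                     cfg: TrainConfig, split_plan: SplitPlan | None = None,
                     holdout_split: int | None = None) -> TrainedModel:
    """Train one per-view network; return the checkpoint with the best
    validation Dice together with the per-epoch history.

    With a split plan, subjects of ``holdout_split`` form the validation set
    and the rest the training set (leave-one-split-out); without one the full
    dataset is used for both (an overfitting sanity mode for tiny cohorts).
    """
    from .evaluation import dice as dice_metric  # late import, avoids cycle

    if split_plan is not None:
        val_ids = [s for s in dataset.subject_ids
                   if split_plan.assignment.get(s) == holdout_split]
        train_ids = [s for s in dataset.subject_ids if s not in set(val_ids)]
        if not train_ids or not val_ids:
            raise ParameterError("split plan leaves an empty train or val set")
        train_set = dataset.subset(train_ids)
        val_set = dataset.subset(val_ids)
    else:
        train_set = val_set = dataset

    rng = np.random.default_rng(cfg.seed)
    builder = build_segmentation_net if spec.attention else build_localization_net
    net = builder(spec, np.random.default_rng(rng.integers(2 ** 31)))
    opt = Adam(net.parameters(), lr=cfg.lr0, betas=cfg.betas, eps=cfg.eps,
               weight_decay=cfg.weight_decay)
    val_volumes = list(val_set.realised_volumes(None, augment=False))

    rows, best = [], (-1.0, -1, None)
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        X, Y, W = train_set.epoch_arrays(view, rng, augment=cfg.augment)
        order = rng.permutation(len(X))
        if cfg.slice_fraction < 1.0:
            order = order[: max(cfg.batch_size,
                                int(round(len(order) * cfg.slice_fraction)))]
        net.train()
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            p = net(Tensor(X[sel]))
            g = Tensor(one_hot(Y[sel], spec.n_classes))
            w = Tensor(W[sel])
            loss = batch_composed_loss(p, g, w, gamma=cfg.gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        net.eval()
        dices = []
        for vol, binlab in val_volumes:
            probs = predict_view_volume(net, vol, view)
            pred = probs.argmax(axis=0) == 1
            dices.append(dice_metric(pred, binlab > 0))
        val_dice = float(np.mean(dices))
        rows.append({"epoch": epoch, "lr": lr,
                     "train_loss": float(np.mean(losses)), "val_dice": val_dice})
        if val_dice > best[0]:
            best = (val_dice, epoch, net.state_dict())
    net.load_state_dict(best[2])
    net.eval()
    history = pd.DataFrame(rows)
    return TrainedModel(net=net, history=history, best_epoch=best[1],
                        best_val_dice=best[0])
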