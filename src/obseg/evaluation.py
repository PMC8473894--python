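"""Segmentation-quality metrics, model ranking and volume agreement.

For binary masks G (ground truth) and P (prediction) on a shared grid:

* Dice           2|G∩P| / (|G|+|P|)                       overlap, higher better
* VS             1 - ||G|-|P|| / (|G|+|P|)                size only, higher better
* AVD (mm)       max of the two directed mean nearest-neighbour Euclidean
                 distances over ALL foreground voxels     boundary, lower better
* R (mm)         Euclidean distance between mask centroids (localization)

Empty-versus-empty pairs score Dice = VS = 1 so that correctly predicted
absent-structure cases count as perfect agreement; AVD is undefined for an
empty mask and raises with an infinity sentinel.

Model comparison ranks each metric ascendingly so the best model receives the
largest rank (ties share the largest tied position), then aggregates by the
geometric mean of per-metric ranks.  Test-retest volume agreement uses the
two-way, absolute-agreement, single-measure intraclass correlation ICC(A,1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import DataError, GeometryError, ParameterError, UndefinedDistanceError
from .image_io import LabelMap


def _as_mask(x) -> np.ndarray:
    if isinstance(x, LabelMap):
        return x.data > 0
    return np.asarray(x) > 0


def _check_pair(g, p):
    gm, pm = _as_mask(g), _as_mask(p)
    if gm.shape != pm.shape:
        raise GeometryError(f"mask grids differ: {gm.shape} vs {pm.shape}")
    if isinstance(g, LabelMap) and isinstance(p, LabelMap):
        if not np.allclose(g.affine, p.affine, atol=1e-3):
            raise GeometryError("mask affines differ")
    return gm, pm


def dice(g, p) -> float:
    """Dice similarity coefficient in [0, 1]; 1 when both masks are empty."""
    gm, pm = _check_pair(g, p)
    ng, np_ = int(gm.sum()), int(pm.sum())
    if ng + np_ == 0:
        return 1.0
    return 2.0 * int((gm & pm).sum()) / (ng + np_)


def volume_similarity(g, p) -> float:
    """1 - ||G|-|P||/(|G|+|P|): size agreement ignoring overlap."""
    gm, pm = _check_pair(g, p)
    ng, np_ = int(gm.sum()), int(pm.sum())
    if ng + np_ == 0:
        return 1.0
    return 1.0 - abs(ng - np_) / (ng + np_)


def avd(g, p, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Average Hausdorff distance (mm) over all foreground voxels."""
    gm, pm = _check_pair(g, p)
    if isinstance(g, LabelMap):
        voxel_size = g.voxel_size
    if not gm.any() or not pm.any():
        raise UndefinedDistanceError("AVD undefined for an empty mask")
    scale = np.asarray(voxel_size, dtype=np.float64)
    gpts = np.argwhere(gm) * scale
    ppts = np.argwhere(pm) * scale
    d_g = cKDTree(ppts).query(gpts)[0].mean()
    d_p = cKDTree(gpts).query(ppts)[0].mean()
    return float(max(d_g, d_p))


def localization_distance(p_centroid, g_centroid, voxel_size=(1.0, 1.0, 1.0)
                          ) -> float:
    """Euclidean distance between two centroid coordinates, in mm."""
    p = np.asarray(p_centroid, dtype=np.float64)
    g = np.asarray(g_centroid, dtype=np.float64)
    scale = np.asarray(voxel_size, dtype=np.float64)
    return float(np.linalg.norm((p - g) * scale))


def evaluate_pair(gt: LabelMap, pred: LabelMap) -> dict:
    """Dice/VS/AVD row for a predicted label map against ground truth."""
    row = {"dice": dice(gt, pred), "vs": volume_similarity(gt, pred)}
    try:
        row["avd_mm"] = avd(gt, pred)
    except UndefinedDistanceError as err:
        row["avd_mm"] = err.value
    return row


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_models(scores: pd.DataFrame, directions: dict,
                ties: str = "max") -> pd.DataFrame:
    """Rank models per metric (ascending; best = n_models) and aggregate by
    the geometric mean of ranks, reported to two decimals.

    ``directions`` maps each metric column to "higher" or "lower" (is
    better).  Tied scores share the largest tied position by default, so two
    equal runner-up models both outrank the next-best rather than averaging.
    """
    if len(scores) < 2:
        raise ParameterError("ranking needs at least 2 models")
    if not directions:
        raise ParameterError("ranking needs at least 1 metric")
    ranks = pd.DataFrame(index=scores.index)
    for metric, direction in directions.items():
        col = pd.to_numeric(scores[metric], errors="coerce")
        if col.isna().any():
            raise DataError(f"non-numeric score in metric {metric!r}")
        values = col.to_numpy(dtype=float)
        if direction == "lower":
            values = -values
        elif direction != "higher":
            raise ParameterError(f"direction must be 'higher' or 'lower', got {direction!r}")
        ranks[f"rank_{metric}"] = stats.rankdata(values, method=ties)
    overall = stats.gmean(ranks.to_numpy(), axis=1)
    out = scores.copy()
    out[ranks.columns] = ranks
    out["overall_rank"] = np.round(overall, 2)
    return out


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc_a1(measurements, confidence: float = 0.95):
    """ICC(A,1): two-way, absolute-agreement, single-measures, with CI.

    ``measurements`` is an n-subjects x k-raters/occasions matrix (complete).
    The coefficient is computed from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    with the standard F-based confidence interval.  Returns
    ``(icc, (lower, upper))``.
    """
    M = np.asarray(measurements, dtype=np.float64)
    if M.ndim != 2:
        raise DataError("measurements must be a 2-D matrix")
    n, k = M.shape
    if n < 2 or k < 2:
        raise DataError("ICC needs at least 2 subjects and 2 measurements")
    if not np.isfinite(M).all():
        raise DataError("measurement matrix contains missing values")
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((M - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0, (1.0, 1.0)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return float(icc), (float(icc), float(icc))
    alpha = 1.0 - confidence
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lower * mse) / (
        f_lower * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_upper * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_upper * msr)
    return float(icc), (float(lower), float(upper))
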