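"""Three-stage inference: localize, crop, ensemble-segment, report volumes.

1. The whole-head volume is conformed to the 0.8 mm working grid (or kept at
   native resolution on request) and down-sampled to 1.6 mm, where three
   per-view localization networks segment a coarse region of interest.  Its
   centroid — mapped through world coordinates back to the working grid —
   centres a 96-cubed crop.
2. Within the crop, every segmentation checkpoint (by default 4 models x 3
   views = 12 networks) produces a per-voxel class-probability volume; the
   ensemble is their unweighted mean, and the final mask the argmax.  Soft
   probabilities are averaged (not hard labels), so only voxels with high
   inter-model agreement survive.
3. The mask is placed back on the input grid, split into left/right by the
   mid-sagittal plane through its centroid, converted to volumes in mm^3 and
   QC-flagged (total volume < 20 mm^3 warrants visual inspection; an empty
   mask is a valid no-OB outcome, not an error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LocalizationError
from .image_io import (CropRecord, LabelMap, PLANES, VolumeImage, conform,
                       crop_with_padding, grids_match, read_volume,
                       reassemble_volume, resample_labels_like, uncrop,
                       write_volume)
from .losses_training import predict_view_volume
from .networks import load_checkpoint
from .roi_labels import Centroid, split_left_right

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    crop_size: tuple = (96, 96, 96)
    working_mm: float = 0.8
    localization_mm: float = 1.6
    native_resolution: bool = False
    qc_volume_threshold_mm3: float = 20.0
    n_models: int = 4
    reduced_ensemble: bool = False
    save_probabilities: bool = False


@dataclass
class SegmentationResult:
    """Final label map in the original input space plus volumetry and QC."""

    labelmap: LabelMap
    volumes_mm3: dict
    qc_flags: set
    provenance: dict

    def as_row(self, subject_id: str) -> dict:
        return {
            "id": subject_id,
            "left_mm3": round(self.volumes_mm3["left"], 3),
            "right_mm3": round(self.volumes_mm3["right"], 3),
            "total_mm3": round(self.volumes_mm3["total"], 3),
            "qc_flags": ";".join(sorted(self.qc_flags)) or "ok",
        }


class OlfactoryBulbPipeline:
    """Bundles localization and segmentation networks with a configuration.

    ``loc_nets`` maps each anatomical view to a localization network;
    ``seg_models`` is a list (one entry per trained model/data-split) of the
    same view->network mapping for the attention segmentation networks.
    """

    def __init__(self, loc_nets: dict, seg_models: list,
                 config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        if set(loc_nets) != set(PLANES):
            raise ConfigurationError(f"localization networks must cover views {PLANES}")
        for model in seg_models:
            if set(model) != set(PLANES):
                raise ConfigurationError(f"each segmentation model must cover views {PLANES}")
        if not self.config.reduced_ensemble and len(seg_models) != self.config.n_models:
            raise ConfigurationError(
                f"expected {self.config.n_models} segmentation models "
                f"({self.config.n_models * 3} checkpoints); got {len(seg_models)}. "
                "Set reduced_ensemble=True to run a smaller ensemble explicitly.")
        self.loc_nets = loc_nets
        self.seg_models = seg_models

    # -- stage 1 --------------------------------------------------------
    def localize(self, working: VolumeImage):
        """Predict the ROI centroid on the working grid.

        Runs the three view networks over the 1.6 mm volume, averages the
        reassembled probability volumes with equal weights, takes the argmax
        ROI mask and maps its centroid through world coordinates.  An empty
        prediction falls back to the anterior-inferior midline and raises
        ``LocalizationError`` carrying that fallback.
        """
        coarse = conform(working, self.config.localization_mm, mode="intensity")
        probs = [predict_view_volume(self.loc_nets[view], coarse, view)
                 for view in PLANES]
        mean_probs = np.mean(probs, axis=0)
        roi = mean_probs.argmax(axis=0) == 1
        if roi.any():
            coarse_centroid = np.argwhere(roi).mean(axis=0)
            fallback = False
        else:
            shape = np.array(coarse.data.shape)
            coarse_centroid = np.array([(shape[0] - 1) / 2.0,
                                        0.75 * (shape[1] - 1),
                                        0.25 * (shape[2] - 1)])
            fallback = True
        world = coarse.affine @ np.append(coarse_centroid, 1.0)
        working_idx = np.linalg.inv(working.affine) @ world
        center = np.clip(np.rint(working_idx[:3]).astype(int), 0,
                         np.array(working.data.shape) - 1)
        centroid = Centroid(coords=tuple(float(c) for c in center),
                            grid_shape=working.data.shape)
        if fallback:
            raise LocalizationError("empty ROI prediction", fallback=centroid)
        return centroid

    # -- stage 2 --------------------------------------------------------
    def ensemble_segment(self, crop: VolumeImage) -> np.ndarray:
        """Unweighted mean of all per-model, per-view probability volumes.

        Returns the (n_classes, X, Y, Z) ensemble probability volume; the OB
        probability is channel 1 and the final mask its argmax.
        """
        acc = None
        count = 0
        for model in self.seg_models:
            for view in PLANES:
                vol = predict_view_volume(model[view], crop, view)
                # accumulate in double precision so the float32 result does
                # not depend on checkpoint ordering
                acc = vol.astype(np.float64) if acc is None else acc + vol
                count += 1
        return (acc / count).astype(np.float32)

    # -- stage 3 --------------------------------------------------------
    def assemble_result(self, mask: np.ndarray, rec: CropRecord,
                        working: VolumeImage, original: VolumeImage,
                        provenance: dict) -> SegmentationResult:
        crop_affine = provenance["crop_affine"]
        crop_lab = LabelMap(mask.astype(np.int16), crop_affine, codes=(0, 1))
        full = uncrop(crop_lab, rec, working.affine)
        if not grids_match(working.affine, working.data.shape,
                           original.affine, original.data.shape):
            full = resample_labels_like(full, original.affine, original.data.shape)
        split = split_left_right(full)
        vox_mm3 = split.voxel_volume_mm3
        left = float((split.data == 1).sum()) * vox_mm3
        right = float((split.data == 2).sum()) * vox_mm3
        total = left + right
        qc = set(provenance.pop("qc_flags", set()))
        if total == 0:
            qc.add("empty_ob")
        elif total < self.config.qc_volume_threshold_mm3:
            qc.add("low_volume")
        return SegmentationResult(
            labelmap=split,
            volumes_mm3={"left": left, "right": right, "total": total},
            qc_flags=qc,
            provenance=provenance,
        )

    # -- end to end -----------------------------------------------------
    def run(self, source: VolumeImage | str | Path) -> SegmentationResult:
        """Full inference on one whole-head volume (path or in-memory)."""
        original = source if isinstance(source, VolumeImage) else read_volume(source)
        if self.config.native_resolution:
            native_mm = float(np.mean(original.voxel_size))
            working = conform(original, native_mm, mode="intensity")
        else:
            working = conform(original, self.config.working_mm, mode="intensity")
        qc_flags = set()
        try:
            centroid = self.localize(working)
        except LocalizationError as err:
            centroid = err.fallback
            qc_flags.add("localization_fallback")
            logger.warning("localization failed; using fallback centroid %s",
                           centroid.coords)
        crop, rec = crop_with_padding(working, centroid.coords,
                                      size=self.config.crop_size)
        ens_probs = self.ensemble_segment(crop)
        mask = ens_probs.argmax(axis=0) == 1
        provenance = {
            "centroid": centroid.coords,
            "crop_record": rec,
            "crop_affine": crop.affine,
            "mean_ob_probability": float(ens_probs[1][mask].mean()) if mask.any() else 0.0,
            "qc_flags": qc_flags,
        }
        result = self.assemble_result(mask, rec, working, original, provenance)
        result.provenance["ob_probability_crop"] = ens_probs[1]
        return result


def load_pipeline(loc_paths: dict, seg_paths: list,
                  config: PipelineConfig | None = None) -> OlfactoryBulbPipeline:
    """Build a pipeline from checkpoint files.

    ``loc_paths`` maps views to localization checkpoints; ``seg_paths`` is a
    list of view->path mappings, one per ensemble model.
    """
    loc_nets = {view: load_checkpoint(p)[0] for view, p in loc_paths.items()}
    seg_models = [{view: load_checkpoint(p)[0] for view, p in model.items()}
                  for model in seg_paths]
    return OlfactoryBulbPipeline(loc_nets, seg_models, config)


def run_pipeline(source, pipeline: OlfactoryBulbPipeline, out_dir=None,
                 subject_id: str = "subject") -> SegmentationResult:
    """Run inference and optionally write the standard output files:
    ``<id>_ob_seg.nii.gz``, optional ``<id>_ob_prob.nii.gz`` and a one-row
    ``volumes.csv`` (id, left_mm3, right_mm3, total_mm3, qc_flags)."""
    result = pipeline.run(source)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(result.labelmap, out_dir / f"{subject_id}_ob_seg.nii.gz")
        if pipeline.config.save_probabilities:
            prob = result.provenance.get("ob_probability_crop")
            if prob is not None:
                prob_vol = VolumeImage(prob.astype(np.float32),
                                       result.provenance["crop_affine"])
                write_volume(prob_vol, out_dir / f"{subject_id}_ob_prob.nii.gz")
        pd.DataFrame([result.as_row(subject_id)]).to_csv(
            out_dir / "volumes.csv", index=False)
    return result
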