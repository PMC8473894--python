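"""Desk-scale end-to-end study: train and evaluate on synthetic cohorts.

The full-scale recipe (64-filter networks, 96-cubed crops, 40 epochs,
hundreds of annotated scans) is far beyond a single CPU, so this module runs
the identical pipeline at a reduced scale chosen to finish in minutes:
16-filter networks, 64-cubed phantoms, 32-cubed localized crops, and around
a dozen training phantoms.  Everything else — the architecture families, the
composed loss with boundary weighting, augmentation before cropping,
stratified splits with leave-one-split-out validation, multi-view soft
ensembling, volumetry and QC — is exactly the production code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import dice, volume_similarity
from .image_io import PLANES, conform
from .losses_training import (SlicePairDataset, TrainConfig,
                              make_stratified_splits, train_view_model)
from .networks import localization_spec, segmentation_spec
from .phantoms import CohortSpec, generate_cohort, generate_no_ob_set, generate_phantom
from .pipeline import OlfactoryBulbPipeline, PipelineConfig
from .roi_labels import RoiSpec, compute_centroid, make_roi_label

logger = logging.getLogger(__name__)

REDUCED_GRID = (64, 64, 64)
REDUCED_CROP = 32
REDUCED_FILTERS = 16


def reduced_train_config(seed: int, epochs: int, crop_size: int | None = REDUCED_CROP,
                         filters: int = REDUCED_FILTERS,
                         slice_fraction: float = 0.5,
                         batch_size: int = 4) -> TrainConfig:
    """Desk-scale schedule: tiny cohorts provide few slices, so smaller
    batches buy the optimisation steps that full-scale training gets from
    hundreds of subjects; half the slice pool is sampled per epoch."""
    return TrainConfig(epochs=epochs, filters=filters,
                       crop_size=crop_size or 0, seed=seed,
                       slice_fraction=slice_fraction, batch_size=batch_size)


def prepare_stage_pairs(specs):
    """Materialise phantoms and derive the two stage-specific datasets.

    Returns ``(seg_pairs, loc_pairs, truth)`` where seg pairs live on the
    0.8 mm working grid, loc pairs on the 1.6 mm grid with the ball-shaped
    ROI label around the OB centroid, and ``truth`` keeps the rasterised
    ground-truth volumes per subject.
    """
    seg_pairs, loc_pairs, truth = [], [], []
    for spec in specs:
        vol, lab = generate_phantom(spec)
        work = conform(vol, 0.8, mode="intensity")
        work_lab = conform(lab, 0.8, mode="label")
        seg_pairs.append((work, work_lab))
        coarse = conform(vol, 1.6, mode="intensity")
        coarse_lab = conform(lab, 1.6, mode="label")
        centroid = compute_centroid(coarse_lab, foreground=(1, 2))
        roi = make_roi_label(centroid, coarse_lab.data.shape, RoiSpec(),
                             affine=coarse_lab.affine)
        loc_pairs.append((coarse, roi))
        truth.append({"volume": vol, "label": lab,
                      "true_total_mm3": float((lab.data > 0).sum())
                      * lab.voxel_volume_mm3})
    return seg_pairs, loc_pairs, truth


@dataclass
class ReducedPipelineBundle:
    pipeline: OlfactoryBulbPipeline
    loc_models: dict
    seg_models: dict
    histories: dict
    split_plan: object


def train_reduced_pipeline(seed: int, n_train: int = 12, loc_epochs: int = 4,
                           seg_epochs: int = 12,
                           holdout_split: int = 3) -> ReducedPipelineBundle:
    """Train localization and segmentation networks on a small cohort and
    bundle them into a runnable pipeline (single-model ensemble, explicitly
    reduced)."""
    ss = np.random.SeedSequence(seed)
    cohort_seed, train_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in ss.spawn(2)]
    specs, table = generate_cohort(CohortSpec(n=n_train, grid_shape=REDUCED_GRID,
                                              seed=cohort_seed))
    seg_pairs, loc_pairs, _ = prepare_stage_pairs(specs)
    ids = table["id"].tolist()
    plan = make_stratified_splits(table, k=4, seed=cohort_seed)

    loc_spec = localization_spec(filters=REDUCED_FILTERS)
    seg_spec = segmentation_spec(filters=REDUCED_FILTERS)
    loc_models, seg_models, histories = {}, {}, {}
    for i, view in enumerate(PLANES):
        cfg = reduced_train_config(seed=train_seed + i, epochs=loc_epochs,
                                   crop_size=None)
        ds = SlicePairDataset(loc_pairs, subject_ids=ids, crop_size=None)
        trained = train_view_model(ds, view, loc_spec, cfg, plan, holdout_split)
        loc_models[view] = trained
        histories[f"loc_{view}"] = trained.history
        logger.info("loc %s best val dice %.3f", view, trained.best_val_dice)
    for i, view in enumerate(PLANES):
        cfg = reduced_train_config(seed=train_seed + 100 + i, epochs=seg_epochs)
        ds = SlicePairDataset(seg_pairs, subject_ids=ids, crop_size=REDUCED_CROP)
        trained = train_view_model(ds, view, seg_spec, cfg, plan, holdout_split)
        seg_models[view] = trained
        histories[f"seg_{view}"] = trained.history
        logger.info("seg %s best val dice %.3f", view, trained.best_val_dice)

    config = PipelineConfig(crop_size=(REDUCED_CROP,) * 3, reduced_ensemble=True)
    pipeline = OlfactoryBulbPipeline(
        loc_nets={v: m.net for v, m in loc_models.items()},
        seg_models=[{v: m.net for v, m in seg_models.items()}],
        config=config)
    return ReducedPipelineBundle(pipeline=pipeline, loc_models=loc_models,
                                 seg_models=seg_models, histories=histories,
                                 split_plan=plan)


def evaluate_pipeline_on_specs(pipeline: OlfactoryBulbPipeline, specs,
                               table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Segment each phantom and score against its rasterised ground truth."""
    rows = []
    for i, spec in enumerate(specs):
        vol, lab = generate_phantom(spec)
        result = pipeline.run(vol)
        gt_total = float((lab.data > 0).sum()) * lab.voxel_volume_mm3
        row = {"id": table["id"].iloc[i] if table is not None else f"sub-{i:03d}",
               "pred_total_mm3": result.volumes_mm3["total"],
               "true_total_mm3": gt_total,
               "dice": dice(lab, result.labelmap),
               "vs": volume_similarity(lab, result.labelmap),
               "qc_flags": ";".join(sorted(result.qc_flags)) or "ok"}
        rows.append(row)
    return pd.DataFrame(rows)


def run_reduced_study(seed: int, n_train: int = 12, n_test: int = 10,
                      n_no_ob: int = 2, loc_epochs: int = 4,
                      seg_epochs: int = 12) -> dict:
    """Train at desk scale, then measure held-out accuracy, volume fidelity,
    no-OB robustness and the identical-checkpoint ensemble identity.

    Returns a dictionary of summary quantities; heavier artefacts (the
    bundle, per-subject tables) ride along under their own keys.
    """
    bundle = train_reduced_pipeline(seed, n_train=n_train, loc_epochs=loc_epochs,
                                    seg_epochs=seg_epochs)
    pipeline = bundle.pipeline
    ss = np.random.SeedSequence(seed + 1)
    test_seed, noob_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                            for s in ss.spawn(2)]
    test_specs, test_table = generate_cohort(
        CohortSpec(n=n_test, grid_shape=REDUCED_GRID, seed=test_seed))
    scores = evaluate_pipeline_on_specs(pipeline, test_specs, test_table)

    no_ob_specs = generate_no_ob_set(n_no_ob, seed=noob_seed,
                                     grid_shape=REDUCED_GRID)
    no_ob_volumes = []
    for spec in no_ob_specs:
        vol, _ = generate_phantom(spec)
        no_ob_volumes.append(pipeline.run(vol).volumes_mm3["total"])

    # an ensemble of identical checkpoints must equal the single model
    quad = OlfactoryBulbPipeline(
        pipeline.loc_nets, [pipeline.seg_models[0]] * 4,
        replace_config(pipeline.config, reduced_ensemble=False, n_models=4))
    probe_vol, _ = generate_phantom(test_specs[0])
    single = pipeline.run(probe_vol)
    stacked = quad.run(probe_vol)
    ens_diff = float(np.abs(
        single.provenance["ob_probability_crop"]
        - stacked.provenance["ob_probability_crop"]).max())

    pred = scores["pred_total_mm3"].to_numpy()
    true = scores["true_total_mm3"].to_numpy()
    corr = float(np.corrcoef(pred, true)[0, 1]) if len(pred) > 1 else float("nan")
    return {
        "holdout_dice_mean": float(scores["dice"].mean()),
        "holdout_vs_mean": float(scores["vs"].mean()),
        "volume_correlation": corr,
        "no_ob_max_volume_mm3": float(max(no_ob_volumes)),
        "ensemble_identity_maxdiff": ens_diff,
        "n_test": int(len(scores)),
        "scores": scores,
        "bundle": bundle,
    }


def replace_config(cfg: PipelineConfig, **kw) -> PipelineConfig:
    data = {**cfg.__dict__, **kw}
    return PipelineConfig(**data)


def overfit_single_phantom(seed: int, epochs: int = 15) -> float:
    """Train one 3-view segmentation model on a single phantom used as both
    train and validation; returns the view-aggregated training Dice.

    A capacity/optimisation sanity check: one model — three per-view
    networks whose probabilities are averaged, the method's smallest unit —
    must be able to memorise a single subject."""
    from .losses_training import predict_view_volume

    specs, _ = generate_cohort(CohortSpec(n=2, grid_shape=REDUCED_GRID, seed=seed))
    seg_pairs, _, _ = prepare_stage_pairs(specs[:1])
    ds = SlicePairDataset(seg_pairs, crop_size=REDUCED_CROP)
    crop_vol, crop_lab = next(ds.realised_volumes(None, augment=False))
    probs = []
    for i, view in enumerate(PLANES):
        cfg = replace(reduced_train_config(seed=seed + i, epochs=epochs,
                                           batch_size=2, slice_fraction=1.0),
                      augment=False)
        trained = train_view_model(ds, view, segmentation_spec(REDUCED_FILTERS),
                                   cfg)
        logger.info("overfit %s best view dice %.3f", view, trained.best_val_dice)
        probs.append(predict_view_volume(trained.net, crop_vol, view))
    aggregated = np.mean(probs, axis=0).argmax(axis=0) == 1
    return dice(crop_lab > 0, aggregated)
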