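"""End-to-end orchestration: simulate → CEST quant → PCA → SVR → evaluate.

A run is fully described by a :class:`~perfph.config.RunConfig`; one master
seed deterministically derives every stage seed, so the same config yields the
same summary on any platform. The run directory is self-describing: it holds
the materialized config, all intermediate maps, a stage-granular log with
voxel-count accounting, and a machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import ROI_LABELS, save_nifti
from .cest import quantify
from .pca import (
    explained_variance_curve,
    fit_pca,
    normalize_and_align,
    pc_score_maps,
    sample_training_voxels,
)
from .regression import SubjectFeatures, evaluate, loso_cv
from .synthetic import generate_cohort, simulate_cohort

logger = logging.getLogger(__name__)

_VARIANCE_SCAN_COMPONENTS = 12


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (all below 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(4, dtype=np.uint32)
    names = ("phantom", "cest", "sampling", "svr")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def run_all(config: RunConfig, out_dir: Path | str, write_phantoms: bool = True) -> dict:
    """Execute the full pipeline and return (and write) the run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    phantom_cfg = dataclasses.replace(config.phantom, seed=seeds["phantom"])
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

    funnel = {"generated": 0, "masked": 0, "valid_curves": 0, "sampled": 0, "predicted": 0}

    stage = "simulate"
    try:
        if write_phantoms:
            generate_cohort(phantom_cfg, out / "phantoms")
        bundles = simulate_cohort(phantom_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    funnel["generated"] = int(np.prod(phantom_cfg.grid_shape)) * phantom_cfg.n_subjects
    funnel["masked"] = int(sum(b.brain_mask.sum() for b in bundles))
    logger.info("simulate: %d subjects on grid %s", len(bundles), phantom_cfg.grid_shape)

    # --- CEST quantification (actual MTR_asym target maps) -----------------
    stage = "cest_quant"
    actual: dict[str, np.ndarray] = {}
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for b in bundles:
        try:
            acq = b.cest
            if config.cest.restrict_to_rois:
                roi_union = np.isin(b.segmentation, list(ROI_LABELS.values()))
                acq = dataclasses.replace(acq, mask=roi_union & b.brain_mask)
            amap, b0map = quantify(acq, n_clusters=config.cest.n_clusters,
                                   seed=seeds["cest"])
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for {b.subject_id}: {exc}") from exc
        actual[b.subject_id] = amap.values
        save_nifti(amap.values, maps_dir / f"{b.subject_id}_mtr_actual.nii.gz",
                   affine=b.cest.affine)
        save_nifti(b0map.shift_ppm, maps_dir / f"{b.subject_id}_b0.nii.gz",
                   affine=b.cest.affine)
    logger.info("cest_quant: %d subjects quantified", len(actual))

    # --- normalization with a cohort-common alignment target ---------------
    stage = "normalize"
    try:
        first_pass = [
            normalize_and_align(b.perfusion, b.brain_mask,
                                bolus_margin=config.pca.bolus_margin)
            for b in bundles
        ]
        target = int(np.median([n.target_index for n in first_pass]))
        norms = [
            normalize_and_align(b.perfusion, b.brain_mask,
                                bolus_margin=config.pca.bolus_margin,
                                target_index=target)
            for b in bundles
        ]
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    funnel["valid_curves"] = int(sum(n.curves.shape[0] for n in norms))
    logger.info("normalize: target frame %d, %d curves kept", target,
                funnel["valid_curves"])

    # --- temporal PCA -------------------------------------------------------
    stage = "pca"
    try:
        cohort = [(b.subject_id, n, b.segmentation) for b, n in zip(bundles, norms)]
        rng = np.random.default_rng(seeds["sampling"])
        sample, provenance = sample_training_voxels(cohort, config.pca.per_roi_sample, rng)
        cum = explained_variance_curve(
            sample, min(_VARIANCE_SCAN_COMPONENTS, sample.shape[1]))
        chosen = int(np.searchsorted(cum, config.pca.variance_target) + 1)
        model = fit_pca(sample, n_components=config.pca.n_components)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    funnel["sampled"] = int(sample.shape[0])
    logger.info("pca: %d sampled curves, %.4f cumulative EVR at %d components",
                sample.shape[0], cum[model.n_components - 1], model.n_components)

    # --- per-subject PC score maps -----------------------------------------
    stage = "pc_scores"
    subject_features = []
    for b, n in zip(bundles, norms):
        try:
            scores = pc_score_maps(n, model)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for {b.subject_id}: {exc}") from exc
        subject_features.append(SubjectFeatures(
            subject_id=b.subject_id, score_maps=scores,
            acidity=actual[b.subject_id], segmentation=b.segmentation))

    # --- LOSO SVR and evaluation -------------------------------------------
    stage = "svr_loso"
    try:
        constructed, fold_prov = loso_cv(
            subject_features, n_per_roi=config.svr.subsample, box=config.svr.box,
            epsilon=config.svr.epsilon, seed=seeds["svr"])
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    for b in bundles:
        save_nifti(constructed[b.subject_id],
                   maps_dir / f"{b.subject_id}_mtr_constructed.nii.gz",
                   affine=b.cest.affine)
    funnel["predicted"] = int(sum(np.isfinite(m).sum() for m in constructed.values()))

    stage = "evaluate"
    try:
        report = evaluate(constructed, actual,
                          {b.subject_id: b.segmentation for b in bundles})
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    report.to_csv(out / "evaluation.csv")
    fold_prov.to_csv(out / "fold_provenance.csv", index=False)

    summary = {
        "package_version": __version__,
        "stage_versions": _stage_versions(),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "alignment_target_frame": target,
        "cumulative_explained_variance": [float(c) for c in cum],
        "chosen_components_for_variance_target": chosen,
        "n_components_used": model.n_components,
        "cohort_mean_spearman_r": report.summary,
        "folds": fold_prov.to_dict(orient="records"),
        "voxel_funnel": funnel,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _stage_versions() -> dict[str, str]:
    import nibabel
    import scipy
    import sklearn

    return {
        "perfph": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }
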