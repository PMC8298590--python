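"""Normalization, alignment and temporal PCA of DSC perfusion curves.

Raw signal-time curves differ across voxels and subjects in baseline level,
bolus depth and bolus timing. Each curve is therefore (1) divided by its
pre-bolus baseline, (2) shifted in time so its bolus minimum lands on a common
target frame, and (3) affinely pinned so baseline -> 1 and minimum -> 0. PCA
over timepoints of the pinned curves then yields a small temporal basis
(seven components by default) whose per-voxel scores summarize curve shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ROI_LABELS, PerfusionSeries

logger = logging.getLogger(__name__)


@dataclass
class NormalizedCurves:
    """Aligned, baseline/depth-pinned curves for the retained voxels.

    Rows satisfy: mean over the pre-bolus window = 1 and min = 0 (both exact
    up to floating point). ``voxels`` holds the (x, y, z) index of each row;
    ``excluded`` marks in-mask voxels dropped for a nonpositive baseline or an
    undetectable bolus.
    """

    curves: np.ndarray            # (n_voxels, n_timepoints)
    voxels: np.ndarray            # (n_voxels, 3) int
    shifts: np.ndarray            # integer frames each curve was moved
    baselines: np.ndarray         # raw pre-bolus baseline per row
    depths: np.ndarray            # relative drop depth per row (1 - min/baseline)
    baseline_frames: int
    target_index: int
    excluded: np.ndarray          # (n_excluded, 3) int
    grid_shape: tuple = ()


@dataclass
class PCModel:
    """Temporal principal components of normalized perfusion curves."""

    mean: np.ndarray                       # (n_timepoints,)
    components: np.ndarray                 # (n_components, n_timepoints), orthonormal
    explained_variance_ratio: np.ndarray   # (n_components,), non-increasing
    n_components: int
    degenerate: bool = False               # zero total variance (non-strict mode)

    def transform(self, curves: np.ndarray) -> np.ndarray:
        """Project curves (rows) onto the components: scores = C (x - mean)."""
        return (np.atleast_2d(curves) - self.mean) @ self.components.T


def detect_baseline_frames(series: PerfusionSeries, mask: np.ndarray) -> int:
    """Pre-bolus frame count: frames before the steepest mean signal drop, minus
    2 as a safety margin, floored at 3."""
    mean_curve = series.data[mask.astype(bool)].mean(axis=0)
    drop = int(np.argmin(np.diff(mean_curve)))
    return max(3, drop - 2)


def _shift_rows(rows: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Shift each row by its integer offset, replicating edge frames."""
    n, t = rows.shape
    idx = np.arange(t)[None, :] - shifts[:, None]
    idx = np.clip(idx, 0, t - 1)
    return np.take_along_axis(rows, idx, axis=1)


def normalize_and_align(series: PerfusionSeries, mask: np.ndarray,
                        baseline_frames: int | None = None,
                        bolus_margin: float = 0.05,
                        target_index: int | None = None) -> NormalizedCurves:
    """Normalize and align every in-mask curve (baseline -> 1, minimum -> 0).

    ``bolus_margin`` is the minimum relative drop below baseline for a bolus to
    count as detected; voxels without one (or with nonpositive baseline) are
    excluded. ``target_index`` fixes the frame the bolus minima are aligned to;
    by default it is the median minimum index of the included voxels, but a
    cohort-level value can be supplied so all subjects share one time axis.
    """
    mask = mask.astype(bool)
    vox = np.argwhere(mask)
    if vox.shape[0] == 0:
        raise ValueError("mask is empty")
    curves = series.data[mask].astype(float)
    bf = baseline_frames if baseline_frames is not None else (
        series.baseline_frames if series.baseline_frames is not None
        else detect_baseline_frames(series, mask))
    if series.n_timepoints < bf + 8:
        raise ValueError("time series too short for the pre-bolus window")

    baseline = curves[:, :bf].mean(axis=1)
    ok = np.isfinite(curves).all(axis=1) & (baseline > 0)
    rel = np.full(curves.shape, np.nan)
    rel[ok] = curves[ok] / baseline[ok, None]
    min_idx = np.nanargmin(np.where(ok[:, None], rel, np.inf), axis=1)
    min_val = rel[np.arange(rel.shape[0]), min_idx]
    has_bolus = ok & (min_val < 1.0 - bolus_margin)
    if not np.any(has_bolus):
        raise ValueError("no voxel shows a detectable bolus")
    n_bad = int((~has_bolus).sum())
    if n_bad:
        logger.info("normalize_and_align: excluding %d/%d voxels", n_bad, len(vox))

    keep = has_bolus
    rel = rel[keep]
    min_idx = min_idx[keep]
    if target_index is None:
        target_index = int(np.median(min_idx))
    shifts = target_index - min_idx
    shifted = _shift_rows(rel, shifts)
    new_base = shifted[:, :bf].mean(axis=1)
    new_min = shifted.min(axis=1)
    span = new_base - new_min
    span[span <= 0] = np.nan
    rows = (shifted - new_min[:, None]) / span[:, None]
    ok2 = np.isfinite(rows).all(axis=1)
    return NormalizedCurves(
        curves=rows[ok2],
        voxels=vox[keep][ok2],
        shifts=shifts[ok2],
        baselines=baseline[keep][ok2],
        depths=(1.0 - min_val[keep][ok2]),
        baseline_frames=bf,
        target_index=target_index,
        excluded=np.concatenate([vox[~keep], vox[keep][~ok2]], axis=0),
        grid_shape=series.grid_shape,
    )


def sample_training_voxels(cohort: list[tuple[str, NormalizedCurves, np.ndarray]],
                           n_per_roi: int, rng: np.random.Generator
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Stratified voxel sample across subjects and tumor subregions.

    ``cohort`` is a list of (subject_id, normalized curves, segmentation
    volume). For every subject and each of ET, NC, ED, up to ``n_per_roi``
    rows are drawn uniformly without replacement. Returns the sampled curve
    matrix and a provenance frame (subject, roi, row index, voxel coords) used
    downstream for leakage auditing.
    """
    blocks: list[np.ndarray] = []
    records: list[dict] = []
    for subject_id, norm, seg in cohort:
        row_labels = seg[tuple(norm.voxels.T)]
        for roi, lab in ROI_LABELS.items():
            rows = np.flatnonzero(row_labels == lab)
            if rows.size == 0:
                logger.warning("subject %s: ROI %s empty, contributes no voxels",
                               subject_id, roi)
                continue
            take = min(n_per_roi, rows.size)
            chosen = rng.choice(rows, size=take, replace=False)
            blocks.append(norm.curves[chosen])
            for r in chosen:
                records.append({
                    "subject": subject_id, "roi": roi, "row": int(r),
                    "x": int(norm.voxels[r, 0]), "y": int(norm.voxels[r, 1]),
                    "z": int(norm.voxels[r, 2]),
                })
    if not blocks:
        raise ValueError("no training voxels could be sampled")
    return np.concatenate(blocks, axis=0), pd.DataFrame.from_records(records)


def fit_pca(curves: np.ndarray, n_components: int = 7, strict: bool = False) -> PCModel:
    """Temporal PCA of curve rows via SVD of the mean-centered matrix.

    Components are ordered by decreasing explained variance; the sign of each
    is fixed so that its largest-magnitude loading is positive, making the
    decomposition reproducible across platforms. Rank-deficient input yields
    fewer usable components (an error in strict mode).
    """
    x = np.asarray(curves, dtype=float)
    if x.ndim != 2:
        raise ValueError("curves must be a 2D matrix (voxels x timepoints)")
    n, t = x.shape
    if n < n_components or t < n_components:
        raise ValueError(f"need at least {n_components} rows and columns")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-30:
        if strict:
            raise ValueError("zero total variance: all curves identical")
        k = min(n_components, t)
        return PCModel(mean=mean, components=np.zeros((k, t)),
                       explained_variance_ratio=np.zeros(k),
                       n_components=k, degenerate=True)
    usable = int(np.sum(s > s[0] * 1e-12))
    if usable < n_components:
        if strict:
            raise ValueError(f"rank {usable} below requested {n_components} components")
        logger.warning("fit_pca: only %d usable components (requested %d)",
                       usable, n_components)
    k = min(n_components, usable)
    comps = vt[:k].copy()
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1.0
    return PCModel(mean=mean, components=comps,
                   explained_variance_ratio=var[:k] / total,
                   n_components=k)


def explained_variance_curve(curves: np.ndarray, max_components: int) -> np.ndarray:
    """Cumulative explained-variance ratio for 1..max_components components."""
    model = fit_pca(curves, n_components=max_components)
    cum = np.cumsum(model.explained_variance_ratio)
    if model.n_components < max_components:  # rank-limited: pad with the total
        cum = np.concatenate([cum, np.full(max_components - model.n_components, cum[-1])])
    return cum


def pc_score_maps(norm: NormalizedCurves, model: PCModel) -> np.ndarray:
    """Per-voxel PC score maps, shape (x, y, z, n_components); NaN where a
    voxel was excluded during normalization."""
    if model.mean.size != norm.curves.shape[1]:
        raise ValueError("model timepoint count must equal curve length")
    scores = model.transform(norm.curves)
    maps = np.full(tuple(norm.grid_shape) + (model.n_components,), np.nan)
    maps[tuple(norm.voxels.T)] = scores
    return maps
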