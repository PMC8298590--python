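"""Per-subregion SVR from temporal PC scores to MTR_asym, with LOSO validation.

For each tumor subregion (ET, NC, ED) a Gaussian-kernel support-vector
regressor maps the seven PC scores of a voxel's perfusion curve to its
MTR_asym value. Models are trained per region on voxels sampled from all
training subjects and evaluated by leave-one-subject-out cross-validation: the
held-out subject's voxels are predicted by the regressor of their own region,
and the stitched prediction over ET ∪ NC ∪ ED is the constructed MTR_asym
image. Agreement with the actual CEST-derived map is scored with Spearman rank
correlation per region and over the union, averaged across subjects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, spearmanr
from sklearn.svm import SVR

from .io import ROI_LABELS

logger = logging.getLogger(__name__)

REGIONS = ("ET", "NC", "ED", "union")
MIN_TRAIN_ROWS = 10
_KSCALE_SUBSAMPLE = 2000
_PERM_EXACT_N = 10  # below this, Spearman p is by exact permutation


@dataclass
class RoiRegressor:
    """A fitted per-region SVR with its feature standardization and provenance."""

    roi: str
    model: SVR
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    kernel_scale: float
    box: float
    epsilon: float
    training_subjects: frozenset = field(default_factory=frozenset)

    @property
    def n_features(self) -> int:
        return self.feat_mean.size

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.feat_mean) / self.feat_sd
        return self.model.predict(x)


def automatic_kernel_scale(features: np.ndarray, rng: np.random.Generator) -> float:
    """Median pairwise Euclidean distance over a subsample of <= 2000 rows."""
    x = np.asarray(features, dtype=float)
    if x.shape[0] > _KSCALE_SUBSAMPLE:
        x = x[rng.choice(x.shape[0], _KSCALE_SUBSAMPLE, replace=False)]
    d = pdist(x)
    med = float(np.median(d)) if d.size else 0.0
    return med if med > 0 else 1.0


def train_svr(features: np.ndarray, targets: np.ndarray, *, roi: str = "",
              box: float = 1.0, epsilon: float | None = None, seed: int = 0,
              training_subjects=()) -> RoiRegressor:
    """Fit an epsilon-insensitive Gaussian-kernel SVR on standardized features.

    The kernel scale is set automatically to the median pairwise distance of
    the (standardized) training rows; epsilon defaults to iqr(targets)/13.49.
    Deterministic given the seed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be 2D with one target per row")
    if x.shape[0] < MIN_TRAIN_ROWS:
        raise ValueError(f"need at least {MIN_TRAIN_ROWS} training rows, got {x.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("features and targets must be finite")
    sd = x.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate features: zero variance in every column")
    mu = x.mean(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd
    rng = np.random.default_rng(seed)
    scale = automatic_kernel_scale(xs, rng)
    if epsilon is None:
        q1, q3 = np.percentile(y, [25, 75])
        epsilon = float(q3 - q1) / 13.49
    model = SVR(kernel="rbf", gamma=1.0 / (2.0 * scale**2), C=box, epsilon=epsilon)
    model.fit(xs, y)
    return RoiRegressor(roi=roi, model=model, feat_mean=mu, feat_sd=sd,
                        kernel_scale=scale, box=box, epsilon=epsilon,
                        training_subjects=frozenset(training_subjects))


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class SubjectFeatures:
    """Per-subject inputs to the regression stage, all on one grid."""

    subject_id: str
    score_maps: np.ndarray     # (x, y, z, n_components), NaN where invalid
    acidity: np.ndarray        # actual MTR_asym values, NaN where invalid
    segmentation: np.ndarray   # 0 / NC 1 / ED 2 / ET 4

    def roi_voxels(self, label: int) -> np.ndarray:
        """Voxels of one ROI with complete features and a valid target."""
        good = (
            (self.segmentation == label)
            & np.all(np.isfinite(self.score_maps), axis=-1)
            & np.isfinite(self.acidity)
        )
        return np.argwhere(good)


def _sample_roi_voxels(subjects: list[SubjectFeatures], n_per_roi: int,
                       seed: int) -> dict[tuple[str, str], np.ndarray]:
    """One fixed per-(subject, ROI) voxel sample reused across all folds."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for si, subj in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si,)))
        for roi, lab in ROI_LABELS.items():
            vox = subj.roi_voxels(lab)
            if vox.shape[0] == 0:
                logger.warning("subject %s has no usable %s voxels", subj.subject_id, roi)
                out[(subj.subject_id, roi)] = vox
                continue
            take = min(n_per_roi, vox.shape[0])
            chosen = np.sort(rng.choice(vox.shape[0], take, replace=False))
            out[(subj.subject_id, roi)] = vox[chosen]  # canonical row order
    return out


def loso_cv(subjects: list[SubjectFeatures], *, n_per_roi: int = 200,
            box: float = 1.0, epsilon: float | None = None, seed: int = 0
            ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Leave-one-subject-out constructed MTR_asym maps.

    For every held-out subject, three per-ROI regressors are trained on the
    other subjects' sampled voxels; the held-out voxels are predicted by the
    regressor of their own ROI and stitched into one map over ET ∪ NC ∪ ED.
    Returns the constructed maps and a fold-provenance frame used for leakage
    auditing (one row per fold × ROI with the training subject list).
    """
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    samples = _sample_roi_voxels(subjects, n_per_roi, seed)

    constructed: dict[str, np.ndarray] = {}
    prov: list[dict] = []
    for test in subjects:
        train_subjects = [s for s in subjects if s.subject_id != test.subject_id]
        out = np.full(test.segmentation.shape, np.nan)
        for roi, lab in ROI_LABELS.items():
            feats, targs, used = [], [], []
            for s in train_subjects:
                vox = samples[(s.subject_id, roi)]
                if vox.shape[0] == 0:
                    continue
                feats.append(s.score_maps[tuple(vox.T)])
                targs.append(s.acidity[tuple(vox.T)])
                used.append(s.subject_id)
            if not feats:
                logger.warning("fold %s: no training data at all for %s",
                               test.subject_id, roi)
                continue
            reg = train_svr(np.concatenate(feats), np.concatenate(targs), roi=roi,
                            box=box, epsilon=epsilon, seed=seed,
                            training_subjects=used)
            assert test.subject_id not in reg.training_subjects
            test_vox = test.roi_voxels(lab)
            if test_vox.shape[0]:
                out[tuple(test_vox.T)] = reg.predict(test.score_maps[tuple(test_vox.T)])
            prov.append({
                "test_subject": test.subject_id, "roi": roi,
                "train_subjects": ",".join(sorted(used)),
                "n_train": sum(samples[(s, roi)].shape[0] for s in used),
                "n_predicted": int(test_vox.shape[0]),
            })
        constructed[test.subject_id] = out
    return constructed, pd.DataFrame.from_records(prov)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _spearman_exact_perm(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r with a two-sided exact permutation p-value (small n)."""
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r_obs = float(rxc @ ryc / denom)
    perms = np.array(list(itertools.permutations(ryc)))
    r_all = perms @ rxc / denom
    p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
    return r_obs, p


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r; p by the large-sample t approximation, exact permutation
    below 10 observations."""
    if x.size < _PERM_EXACT_N:
        return _spearman_exact_perm(x, y)
    r, p = spearmanr(x, y)
    return float(r), float(p)


@dataclass
class EvaluationReport:
    """Per-subject, per-region Spearman agreement and its cohort summary."""

    table: pd.DataFrame        # subject, region, n_voxels, r, p
    summary: dict[str, float]  # region -> unweighted mean r over subjects

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_subject(constructed: np.ndarray, actual: np.ndarray,
                     segmentation: np.ndarray, subject_id: str = "") -> pd.DataFrame:
    """Spearman r between constructed and actual maps per region and union.

    Only voxels where both maps are finite are paired; a region with fewer
    than 3 pairs is marked not-evaluable (NaN r and p).
    """
    if constructed.shape != actual.shape or actual.shape != segmentation.shape:
        raise ValueError("maps and segmentation must share one grid")
    rows = []
    masks = {roi: segmentation == lab for roi, lab in ROI_LABELS.items()}
    masks["union"] = masks["ET"] | masks["NC"] | masks["ED"]
    for region in REGIONS:
        m = masks[region] & np.isfinite(constructed) & np.isfinite(actual)
        n = int(m.sum())
        if n < 3:
            rows.append({"subject": subject_id, "region": region, "n_voxels": n,
                         "r": float("nan"), "p": float("nan")})
            continue
        r, p = spearman_with_p(constructed[m], actual[m])
        rows.append({"subject": subject_id, "region": region, "n_voxels": n,
                     "r": r, "p": p})
    return pd.DataFrame.from_records(rows)


def evaluate(constructed: dict[str, np.ndarray],
             actual: dict[str, np.ndarray],
             segmentations: dict[str, np.ndarray]) -> EvaluationReport:
    """Cohort evaluation: per-subject regional Spearman r, then the unweighted
    mean over subjects per region (ET, NC, ED and their union)."""
    tables = [
        evaluate_subject(constructed[sid], actual[sid], segmentations[sid], sid)
        for sid in constructed
    ]
    table = pd.concat(tables, ignore_index=True)
    summary = {
        region: float(table.loc[table.region == region, "r"].mean())
        for region in REGIONS
    }
    return EvaluationReport(table=table, summary=summary)
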