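"""Curve normalization/alignment and temporal PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

from perfph import pca as ppca
from perfph import synthetic as syn
from perfph.io import PerfusionSeries


def series_from_curves(curves, grid=None, tr=1.5, bf=10):
    """Pack a (V, T) curve matrix into a 4D series with a trivial mask."""
    v, t = curves.shape
    data = curves.reshape(v, 1, 1, t)
    return PerfusionSeries(data=data, tr_seconds=tr, baseline_frames=bf)


class TestNormalizeAlign:
    def test_row_invariants_and_homogeneity(self):
        c = syn.simulate_dsc_curve(150.0, 0.4, 0.8, 18.0, 3.0, 50, 1.5, 10, 0.0)
        curves = np.tile(c, (6, 1))
        norm = ppca.normalize_and_align(series_from_curves(curves),
                                        np.ones((6, 1, 1), bool))
        assert np.allclose(norm.curves[:, :10].mean(axis=1), 1.0, atol=1e-6)
        assert np.allclose(norm.curves.min(axis=1), 0.0, atol=1e-6)
        assert np.all(norm.shifts == 0)
        assert np.allclose(norm.curves, norm.curves[0])

    def test_scale_invariance(self):
        """Replacing L by 2L leaves the normalized row unchanged (noise-free)."""
        rows = np.stack([
            syn.simulate_dsc_curve(L, 0.4, 0.7, 18.0, 3.0, 50, 1.5, 10, 0.0)
            for L in (200.0, 400.0)
        ])
        norm = ppca.normalize_and_align(series_from_curves(rows),
                                        np.ones((2, 1, 1), bool))
        assert np.allclose(norm.curves[0], norm.curves[1], atol=1e-12)

    def test_flat_curve_flagged(self):
        rows = np.stack([
            syn.simulate_dsc_curve(200.0, 0.5, 0.8, 18.0, 3.0, 50, 1.5, 10, 0.0),
            np.full(50, 180.0),  # no bolus
        ])
        norm = ppca.normalize_and_align(series_from_curves(rows),
                                        np.ones((2, 1, 1), bool))
        assert norm.curves.shape[0] == 1
        assert norm.excluded.shape[0] == 1

    def test_all_flat_errors(self):
        rows = np.full((4, 50), 100.0)
        with pytest.raises(ValueError, match="bolus"):
            ppca.normalize_and_align(series_from_curves(rows),
                                     np.ones((4, 1, 1), bool))

    def test_alignment_to_target_index(self):
        base = syn.simulate_dsc_curve(200.0, 0.5, 0.9, 18.0, 3.0, 60, 1.5, 10, 0.0)
        shifted = np.roll(base, 4)
        shifted[:4] = base[0]
        norm = ppca.normalize_and_align(series_from_curves(np.stack([base, shifted])),
                                        np.ones((2, 1, 1), bool))
        assert np.argmin(norm.curves[0]) == np.argmin(norm.curves[1]) == norm.target_index


class TestSampling:
    def build_cohort(self, n_rows=40):
        rng = np.random.default_rng(0)
        curves = rng.normal(size=(n_rows, 30))
        norm = ppca.NormalizedCurves(
            curves=curves, voxels=np.argwhere(np.ones((n_rows, 1, 1), bool)),
            shifts=np.zeros(n_rows, int), baselines=np.ones(n_rows),
            depths=np.ones(n_rows), baseline_frames=5, target_index=10,
            excluded=np.empty((0, 3), int), grid_shape=(n_rows, 1, 1))
        seg = np.zeros((n_rows, 1, 1), dtype=int)
        seg[:10] = 1   # NC
        seg[10:30] = 2  # ED
        seg[30:] = 4   # ET
        return [("s1", norm, seg)]

    def test_clamps_to_roi_size(self):
        x, prov = ppca.sample_training_voxels(self.build_cohort(), 100,
                                              np.random.default_rng(1))
        assert x.shape[0] == 40  # every stratum exhausted
        assert prov.roi.value_counts().to_dict() == {"ED": 20, "NC": 10, "ET": 10}

    def test_deterministic_given_seed(self):
        cohort = self.build_cohort()
        x1, p1 = ppca.sample_training_voxels(cohort, 5, np.random.default_rng(7))
        x2, p2 = ppca.sample_training_voxels(cohort, 5, np.random.default_rng(7))
        assert np.array_equal(x1, x2)
        assert p1.equals(p2)

    def test_count_bound_and_provenance(self):
        cohort = self.build_cohort() * 1
        x, prov = ppca.sample_training_voxels(cohort, 8, np.random.default_rng(3))
        assert x.shape[0] <= 3 * 8
        assert set(prov.columns) >= {"subject", "roi", "row", "x", "y", "z"}
        # provenance points back at the sampled rows
        norm = cohort[0][1]
        for rec in prov.itertuples():
            assert np.array_equal(x[rec.Index], norm.curves[rec.row])


class TestFitPca:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=20)
        v /= np.linalg.norm(v)
        a = rng.normal(size=(30, 1))
        x = 5.0 + a * v
        model = ppca.fit_pca(x, n_components=3, strict=False)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(model.components[0] @ v) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_strict_raises(self):
        x = np.tile(np.arange(12.0), (15, 1))
        with pytest.raises(ValueError, match="variance"):
            ppca.fit_pca(x, n_components=3, strict=True)
        model = ppca.fit_pca(x, n_components=3, strict=False)
        assert model.degenerate

    def test_matches_eigendecomposition_oracle(self):
        """Independent oracle: full eigendecomposition of the time-time
        covariance matrix."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 20))
        model = ppca.fit_pca(x, n_components=7)
        cov = np.cov(x, rowvar=False, bias=True)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        oracle_ratio = evals / evals.sum()
        assert np.allclose(model.explained_variance_ratio, oracle_ratio[:7],
                           atol=1e-8)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(25, 12))
        model = ppca.fit_pca(x, n_components=12)
        recon = model.mean + model.transform(x) @ model.components
        assert np.allclose(recon, x, atol=1e-8)

    def test_ratio_properties(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(40, 10)) * np.linspace(3, 0.1, 10)
        model = ppca.fit_pca(x, n_components=10)
        r = model.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)          # non-increasing
        assert r.sum() == pytest.approx(1.0, abs=1e-9)
        cum = ppca.explained_variance_curve(x, 10)
        assert np.all(np.diff(cum) >= -1e-12)       # truncation sum monotone

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(arrays(np.float64, (15, 8), elements=st.floats(-5, 5)))
    def test_orthonormal_and_sign_fixed(self, x):
        x = x + np.arange(8)  # avoid the all-identical degenerate case
        model = ppca.fit_pca(x, n_components=3, strict=False)
        if model.degenerate:
            return
        k = model.components.shape[0]
        assert np.allclose(model.components @ model.components.T, np.eye(k),
                           atol=1e-8)
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] >= 0


class TestScores:
    def test_centering_and_orthonormality(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 16))
        model = ppca.fit_pca(x, n_components=4)
        assert np.allclose(model.transform(model.mean), 0.0, atol=1e-10)
        curve = model.mean + 2.0 * model.components[0]
        assert np.allclose(model.transform(curve),
                           [2.0, 0.0, 0.0, 0.0], atol=1e-10)

    def test_score_maps_shape_and_nan(self, noisefree_bundle):
        b = noisefree_bundle
        norm = ppca.normalize_and_align(b.perfusion, b.brain_mask)
        model = ppca.fit_pca(norm.curves, n_components=5)
        maps = ppca.pc_score_maps(norm, model)
        assert maps.shape == b.perfusion.grid_shape + (5,)
        assert np.isnan(maps[~b.brain_mask]).all()
        assert np.isfinite(maps[tuple(norm.voxels.T)]).all()

    def test_pc1_tracks_perfusion_level(self, noisefree_cohort):
        """The first temporal PC of tumor-ROI curves orders voxels by the
        latent perfusion level (noise-free phantom)."""
        norms = [ppca.normalize_and_align(b.perfusion, b.brain_mask)
                 for b in noisefree_cohort]
        cohort = [(b.subject_id, n, b.segmentation)
                  for b, n in zip(noisefree_cohort, norms)]
        x, _ = ppca.sample_training_voxels(cohort, 500, np.random.default_rng(0))
        model = ppca.fit_pca(x, n_components=7)
        b, norm = noisefree_cohort[0], norms[0]
        scores = model.transform(norm.curves)
        level = b.truth.L[tuple(norm.voxels.T)]
        rho = spearmanr(scores[:, 0], level).statistic
        assert rho >= 0.8
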