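"""CEST quantification: B0 estimation, spectral correction, MTR_asym maps."""

import numpy as np
import pytest

from perfph import cest
from perfph import synthetic as syn
from perfph.cest import (
    AcidityMap,
    B0Map,
    correct_spectrum,
    estimate_b0,
    mtr_asym_map,
    window_integral,
)

from conftest import build_acquisition

SHAPE = (6, 6, 3)


def acidity_grid(shape=SHAPE, hi=0.08):
    return np.linspace(0.0, hi, int(np.prod(shape))).reshape(shape)


class TestEstimateB0:
    def test_zero_field_recovered(self, offsets):
        acq = build_acquisition(np.zeros(SHAPE), 0.0, offsets)
        b0map = estimate_b0(acq, n_clusters=2)
        assert np.abs(b0map.shift_ppm).max() < 1e-6
        assert not b0map.flagged.any()

    def test_constant_shift_recovered(self, offsets):
        acq = build_acquisition(acidity_grid(), 0.2, offsets)
        b0map = estimate_b0(acq, n_clusters=4)
        err = np.abs(b0map.shift_ppm[acq.mask] - 0.2)
        assert err.max() < 0.01

    def test_single_cluster_degenerates_gracefully(self, offsets):
        acq = build_acquisition(acidity_grid(), -0.1, offsets)
        b0map = estimate_b0(acq, n_clusters=1)
        assert b0map.mask.sum() == acq.mask.sum()
        assert np.abs(b0map.shift_ppm[acq.mask] + 0.1).max() < 0.01

    def test_too_few_voxels_raises(self, offsets):
        acq = build_acquisition(np.zeros((2, 2, 1)), 0.0, offsets)
        with pytest.raises(ValueError, match="clusters"):
            estimate_b0(acq, n_clusters=10)

    def test_nonfinite_spectrum_flagged_and_excluded(self, offsets):
        acq = build_acquisition(acidity_grid(), 0.0, offsets)
        acq.saturated[0, 0, 0, 5] = np.nan
        b0map = estimate_b0(acq, n_clusters=2)
        assert b0map.flagged[0, 0, 0]
        assert not b0map.mask[0, 0, 0]
        amap = mtr_asym_map(acq, b0map)
        assert not amap.valid[0, 0, 0]
        assert np.isnan(amap.values[0, 0, 0])


class TestCorrectSpectrum:
    def test_zero_shift_is_identity(self, offsets):
        z, _ = syn.simulate_zspectrum(0.03, 0.0, offsets, 0.0)
        assert np.array_equal(correct_spectrum(z, 0.0, offsets), z)

    def test_roundtrip_against_generator(self, offsets):
        """Correcting a spectrum measured under b0=0.2 recovers the unshifted
        generator spectrum within interpolation tolerance."""
        measured, _ = syn.simulate_zspectrum(0.05, 0.2, offsets, 0.0)
        nominal, _ = syn.simulate_zspectrum(0.05, 0.0, offsets, 0.0)
        corrected = correct_spectrum(measured, 0.2, offsets)
        good = np.isfinite(corrected)
        assert good.sum() >= 20
        assert np.abs(corrected[good] - nominal[good]).max() < 1e-3

    def test_support_edge_marked_missing(self, offsets):
        z, _ = syn.simulate_zspectrum(0.0, 0.3, offsets, 0.0)
        corrected = correct_spectrum(z, 0.3, offsets)
        assert np.isnan(corrected[offsets == 3.5])
        assert np.isfinite(corrected[offsets == 2.8])

    def test_idempotent_after_correction(self, offsets):
        z, _ = syn.simulate_zspectrum(0.05, 0.1, offsets, 0.0)
        once = correct_spectrum(z, 0.1, offsets)
        again = correct_spectrum(once, 0.0, offsets)
        assert np.array_equal(once, again, equal_nan=True)


class TestWindowIntegral:
    def test_constant_spectrum(self, offsets):
        assert window_integral(np.full(29, 0.7), offsets, 3.0) == pytest.approx(0.7)
        assert window_integral(np.full(29, 0.7), offsets, -3.0) == pytest.approx(0.7)

    def test_five_point_mean(self, offsets):
        spec = np.zeros(29)
        for w, v in zip((2.8, 2.9, 3.0, 3.1, 3.2), (0.5, 0.6, 0.7, 0.6, 0.5)):
            spec[offsets == w] = v
        assert window_integral(spec, offsets, 3.0) == pytest.approx(0.58)

    def test_missing_point_uses_remaining(self, offsets):
        spec = np.zeros(29)
        for w, v in zip((2.8, 2.9, 3.0, 3.1, 3.2), (0.5, 0.6, 0.7, 0.6, 0.5)):
            spec[offsets == w] = v
        spec[offsets == 3.0] = np.nan
        assert window_integral(spec, offsets, 3.0) == pytest.approx(0.55)

    def test_empty_window_signals_exclusion(self, offsets):
        spec = np.full(29, np.nan)
        assert np.isnan(window_integral(spec, offsets, 3.0))


class TestMtrAsym:
    def test_direct_substitution(self, offsets):
        """W(-3)=0.6*S0 and W(+3)=0.5*S0 must give 0.1."""
        shape = (2, 2, 1)
        sat = np.zeros(shape + (29,))
        sat[..., np.abs(offsets + 3.0) <= 0.21] = 1.2  # S0 = 2 below
        sat[..., np.abs(offsets - 3.0) <= 0.21] = 1.0
        sat[..., np.abs(offsets) <= 0.31] = 0.4
        acq = cest.CestAcquisition(offsets=offsets, saturated=sat,
                                   s0=np.full(shape, 2.0),
                                   mask=np.ones(shape, bool))
        b0map = B0Map(shift_ppm=np.zeros(shape), flagged=np.zeros(shape, bool),
                      mask=np.ones(shape, bool))
        amap = mtr_asym_map(acq, b0map)
        assert np.allclose(amap.values, 0.1)

    def test_null_phantom_is_machine_zero(self, offsets):
        acq = build_acquisition(np.zeros(SHAPE), 0.0, offsets)
        amap, _ = cest.quantify(acq, n_clusters=2)
        assert np.nanmax(np.abs(amap.values)) < 1e-9

    def test_mirror_antisymmetry(self, offsets):
        """Mirroring every spectrum about 0 ppm negates the map."""
        acq = build_acquisition(acidity_grid(), 0.1, offsets)
        b0map = estimate_b0(acq, n_clusters=3)
        base = mtr_asym_map(acq, b0map)
        mirrored = cest.CestAcquisition(
            offsets=offsets, saturated=acq.saturated[..., ::-1].copy(),
            s0=acq.s0, mask=acq.mask)
        flipped = B0Map(shift_ppm=-b0map.shift_ppm, flagged=b0map.flagged,
                        mask=b0map.mask)
        neg = mtr_asym_map(mirrored, flipped)
        assert np.allclose(neg.values, -base.values, atol=1e-12, equal_nan=True)

    def test_calibration_sweep_recovery(self, offsets):
        """Noise-free, B0-free sweep: recovered MTR_asym within 5% of truth."""
        acid = acidity_grid()
        amap, _ = cest.quantify(build_acquisition(acid, 0.0, offsets), n_clusters=4)
        informative = acid > 0.005
        rel = np.abs(amap.values - acid)[informative] / acid[informative]
        assert rel.max() < 0.05

    def test_b0_correction_beats_no_correction(self, offsets):
        """With a 0.2 ppm field, correction brings nearly every voxel closer
        to the true acidity than leaving spectra uncorrected."""
        rng = np.random.default_rng(4)
        shape = (8, 8, 4)
        acid = rng.uniform(0.01, 0.07, size=shape)
        field = syn.make_b0_field(shape, 0.2, np.random.default_rng(1))
        acq = build_acquisition(acid, field, offsets)
        b0map = estimate_b0(acq, n_clusters=6)
        corrected = mtr_asym_map(acq, b0map)
        uncorrected = mtr_asym_map(acq, B0Map(
            shift_ppm=np.zeros(shape), flagged=np.zeros(shape, bool),
            mask=np.ones(shape, bool)))
        err_c = np.abs(corrected.values - acid)
        err_u = np.abs(uncorrected.values - acid)
        both = corrected.valid & uncorrected.valid
        # voxels on the field's zero-crossing are ties at the 1e-5 level;
        # a 1e-4 margin (noise floor of the estimate) separates real losses
        assert np.mean(err_c[both] <= err_u[both] + 1e-4) >= 0.99

    def test_nonpositive_s0_excluded(self, offsets):
        acq = build_acquisition(acidity_grid(), 0.0, offsets)
        amap, b0map = cest.quantify(acq, n_clusters=2)
        acq.s0[1, 1, 1] = 0.0  # after validation; simulates a dead voxel
        amap2 = mtr_asym_map(acq, b0map)
        assert not amap2.valid[1, 1, 1]
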