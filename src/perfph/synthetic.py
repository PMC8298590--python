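"""Digital phantom cohorts: DSC time-series, CEST z-spectra and tumor masks.

Each synthetic subject carries a glioblastoma-like lesion built from concentric
ellipsoids (necrotic core NC, enhancing-tumor rim ET, edema shell ED) inside a
brain ellipsoid. Every voxel has a latent hemodynamic vector
(perfusion level L, drop depth D, recovery fraction R, bolus arrival t0,
sharpness k); a stated monotone link maps (L, D, R) to a true voxel acidity on
the fractional MTR_asym scale, which in turn sets the amine-pool amplitude of a
three-pool Lorentzian z-spectrum. A smooth polynomial B0 field shifts all
spectra. The full latent state is returned as ``PhantomTruth`` so downstream
recovery can be scored against ground truth.

Within a tissue class the latents L, D and R are driven jointly by one uniform
"severity" variate per voxel, while bolus timing (t0) and sharpness (k) carry
independent jitter. The shared severity is what makes the curve *shape* that
survives per-voxel amplitude normalization informative about perfusion level
and about the acidity link — mirroring the empirical observation that temporal
principal components of perfusion curves track tissue state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PhantomConfig
from .io import (
    LABEL_ED,
    LABEL_ET,
    LABEL_NC,
    CestAcquisition,
    PerfusionSeries,
    save_nifti,
    save_offsets,
)

# truth label codes (segmentation files only carry the tumor labels)
TRUTH_BACKGROUND = 0
TRUTH_NORMAL = 5

# ---------------------------------------------------------------------------
# z-spectral pool model
# ---------------------------------------------------------------------------

#: Lorentzian pools: direct water saturation, a broad symmetric MT-like
#: background, and the pH-sensitive amine pool at +3 ppm. Amplitudes are
#: fractions of S0; widths are full widths at half maximum in ppm.
WATER_AMP, WATER_FWHM = 0.82, 1.4
MT_AMP, MT_FWHM = 0.06, 40.0
AMINE_DELTA, AMINE_FWHM = 3.0, 1.0

#: Acidity-link constants: acidity = ACIDITY_MAX * (wL*nL + wD*D + wR*(1-R)),
#: nL = clip((L - 60) / 300, 0, 1). Monotone increasing in L and D,
#: decreasing in R.
ACIDITY_MAX = 0.08
LINK_WEIGHTS = {"L": 0.35, "D": 0.30, "R": 0.35}
L_NORM_RANGE = (60.0, 360.0)

#: Hemodynamic latents are driven by a single "severity" scale u in [0, 1]:
#: every tissue class draws u uniformly from its own sub-interval, and the
#: global monotone maps below turn u into perfusion level L, drop depth D and
#: recovery fraction R. Tying L, D and R to one scale (rather than sampling
#: them independently) is what makes the curve shape that survives per-voxel
#: amplitude normalization carry information about perfusion level — the
#: empirical signature the temporal PCs exploit. Bolus sharpness k and arrival
#: t0 are jittered independently of u.
TISSUE_SEVERITY = {
    TRUTH_NORMAL: (0.25, 0.55),
    LABEL_NC: (0.05, 0.40),   # necrosis: lowest perfusion
    LABEL_ED: (0.35, 0.75),   # edema: intermediate
    LABEL_ET: (0.60, 1.00),   # enhancing tumor: high level and depth
}
LATENT_MAPS = {"L": (80.0, 340.0), "D": (0.15, 0.75), "R": (0.50, 0.95)}
K_RANGE = (2.5, 4.5)


def offset_schedule() -> np.ndarray:
    """The 29-point saturation-offset schedule in ppm, sorted ascending.

    Union of three arithmetic ranges at 0.1 ppm increments:
    -3.5…-2.5 (negative shoulder), -0.3…+0.3 (water window) and +2.5…+3.5
    (amine shoulder); 11 + 7 + 11 = 29 unique offsets.
    """
    ranges = [(-3.5, -2.5), (-0.3, 0.3), (2.5, 3.5)]
    vals = np.concatenate(
        [np.round(np.arange(lo, hi + 0.05, 0.1), 1) for lo, hi in ranges]
    )
    out = np.unique(vals)
    out[out == 0.0] = 0.0  # normalize -0.0
    return out


def _lorentzian(omega: np.ndarray, delta: float, fwhm: float) -> np.ndarray:
    """Unit-amplitude Lorentzian absorption line centered at ``delta``."""
    hw2 = (fwhm / 2.0) ** 2
    return hw2 / (hw2 + (np.asarray(omega) - delta) ** 2)


def amine_calibration() -> float:
    """Window-asymmetry of a unit-amplitude amine line on the standard schedule.

    With symmetric water/MT pools cancelling exactly between the ±3 ppm
    windows, a noise-free, B0-free spectrum with amine amplitude A yields
    MTR_asym = A * amine_calibration(); the generator therefore uses
    A = true_acidity / amine_calibration() so recovered MTR_asym equals the
    true acidity.
    """
    offsets = offset_schedule()
    pos = np.abs(offsets - AMINE_DELTA) <= 0.2 + 1e-9
    neg = np.abs(offsets + AMINE_DELTA) <= 0.2 + 1e-9
    line = _lorentzian(offsets, AMINE_DELTA, AMINE_FWHM)
    return float(line[pos].mean() - line[neg].mean())


_W_CAL = amine_calibration()


def zspectrum_model(omega, true_acidity, b0=0.0) -> np.ndarray:
    """Noise-free z-spectrum Z(w) of the three-pool model, S0-normalized.

    ``omega`` may be any array of offsets (ppm); ``true_acidity`` and ``b0``
    broadcast against each other and against a leading voxel axis.
    """
    omega = np.asarray(omega, dtype=float)
    scalar = np.ndim(true_acidity) == 0 and np.ndim(b0) == 0
    acid = np.atleast_1d(np.asarray(true_acidity, dtype=float))[..., None]
    b0 = np.atleast_1d(np.asarray(b0, dtype=float))[..., None]
    amp_amine = acid / _W_CAL
    if np.any(WATER_AMP + MT_AMP + amp_amine > 1.0):
        raise ValueError("pool amplitudes sum above 1 (nonphysical negative signal)")
    w = omega[None, :] - b0
    z = (
        1.0
        - WATER_AMP * _lorentzian(w, 0.0, WATER_FWHM)
        - MT_AMP * _lorentzian(w, 0.0, MT_FWHM)
        - amp_amine * _lorentzian(w, AMINE_DELTA, AMINE_FWHM)
    )
    return z[0] if scalar else z


def simulate_zspectrum(true_acidity, b0, offsets, noise_sd: float, rng=None):
    """Simulate a saturated z-spectrum and its unsaturated reference S0.

    Returns ``(spectrum, s0)``; per-voxel arrays broadcast. S0 is 1 in
    arbitrary units before noise; noise is i.i.d. Gaussian with standard
    deviation ``noise_sd`` (fraction of S0) on every saturated sample and on
    S0 itself.
    """
    offsets = np.asarray(offsets, dtype=float)
    z = zspectrum_model(offsets, true_acidity, b0)
    s0 = np.ones(z.shape[:-1]) if z.ndim > 1 else 1.0
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
        s0 = s0 + rng.normal(0.0, noise_sd, size=np.shape(s0))
    return z, s0


# ---------------------------------------------------------------------------
# DSC curve model
# ---------------------------------------------------------------------------

def gamma_variate(t, t0, k):
    """Unit-peak gamma-variate bolus; zero for t <= t0.

    Shape alpha = k; time-to-peak tp = t0 + 12/k seconds, so larger sharpness
    gives a steeper, earlier bolus.
    """
    t = np.asarray(t, dtype=float)
    t0 = np.atleast_1d(np.asarray(t0, dtype=float))[..., None]
    k = np.atleast_1d(np.asarray(k, dtype=float))[..., None]
    ttp = 12.0 / k
    x = (t[None, :] - t0) / ttp
    g = np.where(x > 0, np.power(np.clip(x, 1e-300, None), k) * np.exp(k * (1.0 - x)), 0.0)
    return g


def simulate_dsc_curve(L, D, R, t0, k, n_timepoints: int, tr: float,
                       baseline_frames: int, noise_sd: float, rng=None):
    """Simulate signal-time curves L*(1 - D*g(t) - D*(1-R)*c(t)) + noise.

    ``g`` is a unit-peak gamma-variate bolus and ``c(t) = 1 - g(t)`` for
    t >= t_peak (zero before) — a smoothed step modelling incomplete signal
    recovery from leakage. The noise-free curve equals L on the pre-bolus
    baseline, dips to exactly L*(1-D) at the bolus peak, and plateaus at
    L*(1 - D*(1-R)) at late times. Scalar latents give one curve; arrays of
    shape (V,) give a (V, T) matrix.
    """
    scalar = np.ndim(L) == 0
    L, D, R, t0, k = (np.atleast_1d(np.asarray(a, dtype=float)) for a in (L, D, R, t0, k))
    if np.any(L <= 0):
        raise ValueError("perfusion level L must be positive")
    if np.any(t0 < baseline_frames * tr):
        raise ValueError("bolus arrival t0 must not precede the pre-bolus baseline window")
    t = np.arange(n_timepoints) * tr
    g = gamma_variate(t, t0, k)
    tp = (t0 + 12.0 / k)[:, None]
    c = np.where(t[None, :] >= tp, 1.0 - g, 0.0)
    curve = L[:, None] * (1.0 - D[:, None] * g - (D * (1.0 - R))[:, None] * c)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        curve = curve + rng.normal(0.0, 1.0, size=curve.shape) * (noise_sd * L)[:, None]
    return curve[0] if scalar else curve


# ---------------------------------------------------------------------------
# geometry, fields, acidity link
# ---------------------------------------------------------------------------

def _ellipsoid_mask(grid_shape, center, semi) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    q = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return q <= 1.0


def make_tissue_labels(grid_shape) -> np.ndarray:
    """Truth label volume: background 0, normal brain 5, NC 1, ED 2, ET 4.

    Brain is a centered ellipsoid; the lesion is a set of concentric
    ellipsoids (NC core, ET rim, ED shell) displaced into one hemisphere.
    Each tumor class is guaranteed non-empty.
    """
    nx, ny, nz = grid_shape
    center = tuple((s - 1) / 2.0 for s in grid_shape)
    brain = _ellipsoid_mask(grid_shape, center, tuple(0.45 * s for s in grid_shape))
    tcen = (0.60 * nx, 0.42 * ny, 0.50 * nz)
    ed = _ellipsoid_mask(grid_shape, tcen, (0.28 * nx, 0.28 * ny, 0.30 * nz))
    et = _ellipsoid_mask(grid_shape, tcen, (0.18 * nx, 0.18 * ny, 0.21 * nz))
    nc = _ellipsoid_mask(grid_shape, tcen, (0.10 * nx, 0.10 * ny, 0.12 * nz))
    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[brain] = TRUTH_NORMAL
    labels[ed & brain] = LABEL_ED
    labels[et & brain] = LABEL_ET
    labels[nc & brain] = LABEL_NC
    # tiny grids: force at least one voxel per tumor class near the center
    ci = tuple(min(int(round(c)), s - 1) for c, s in zip(tcen, grid_shape))
    fallback = [LABEL_NC, LABEL_ET, LABEL_ED]
    for off, lab in enumerate(fallback):
        if not np.any(labels == lab):
            labels[min(ci[0] + off, nx - 1), ci[1], ci[2]] = lab
    return labels


def make_b0_field(grid_shape, amplitude_ppm: float, rng, mask=None) -> np.ndarray:
    """Smooth low-order polynomial B0 field scaled to ``amplitude_ppm``.

    A random quadratic in normalized coordinates, rescaled so its maximum
    absolute value over ``mask`` (the whole grid when None) equals the
    amplitude.
    """
    if amplitude_ppm == 0:
        rng.normal(size=9)  # keep the stream position independent of amplitude
        return np.zeros(grid_shape)
    coords = [np.linspace(-1.0, 1.0, s) for s in grid_shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    basis = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coef = rng.normal(size=9)
    p = sum(c * b for c, b in zip(coef, basis))
    ref = np.max(np.abs(p if mask is None else p[mask]))
    return amplitude_ppm * p / ref


def acidity_link(L, D, R) -> np.ndarray:
    """Monotone hemodynamics→acidity link (fractional MTR_asym scale).

    Increasing in perfusion level and drop depth, decreasing in recovery
    fraction: highly perfused, leaky tissue is modelled as most acidic.
    """
    lo, hi = L_NORM_RANGE
    n_l = np.clip((np.asarray(L, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    w = LINK_WEIGHTS
    return ACIDITY_MAX * (w["L"] * n_l + w["D"] * np.asarray(D) + w["R"] * (1.0 - np.asarray(R)))


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth of one synthetic subject (full-grid arrays)."""

    L: np.ndarray
    D: np.ndarray
    R: np.ndarray
    t0: np.ndarray
    k: np.ndarray
    true_acidity: np.ndarray
    b0_field: np.ndarray
    label: np.ndarray  # truth codes: 0 bg, 5 normal, 1 NC, 2 ED, 4 ET
    link: dict = field(default_factory=dict)

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in
                ("L", "D", "R", "t0", "k", "true_acidity", "b0_field", "label")}


@dataclass
class SubjectBundle:
    subject_id: str
    perfusion: PerfusionSeries
    cest: CestAcquisition
    segmentation: np.ndarray  # 0 / NC 1 / ED 2 / ET 4
    brain_mask: np.ndarray
    truth: PhantomTruth


def simulate_subject(config: PhantomConfig, subject_index: int) -> SubjectBundle:
    """Generate one subject; deterministic given (config.seed, subject_index)."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_index,))
    rng = np.random.default_rng(ss)
    shape = config.grid_shape
    labels = make_tissue_labels(shape)
    brain = labels > 0
    n_vox = int(brain.sum())

    severity = np.zeros(shape)
    u_all = rng.uniform(size=n_vox)
    severity[brain] = u_all
    for lab, (lo, hi) in TISSUE_SEVERITY.items():
        m = labels == lab
        severity[m] = lo + (hi - lo) * severity[m]
    L = np.zeros(shape)
    D = np.zeros(shape)
    R = np.ones(shape)
    for name, (lo, hi) in LATENT_MAPS.items():
        tgt = {"L": L, "D": D, "R": R}[name]
        tgt[brain] = lo + (hi - lo) * severity[brain]
    k = np.zeros(shape)
    k[brain] = rng.uniform(*K_RANGE, size=n_vox)
    t0 = np.zeros(shape)
    t0[brain] = (config.baseline_frames + rng.uniform(0.5, 2.5, size=n_vox)) * config.tr_seconds

    acidity = np.zeros(shape)
    acidity[brain] = acidity_link(L[brain], D[brain], R[brain])
    if config.link_noise_sd > 0:
        acidity[brain] = np.clip(
            acidity[brain] + rng.normal(0.0, config.link_noise_sd, size=n_vox), 0.0, 0.1
        )
    b0 = make_b0_field(shape, config.b0_amplitude_ppm, rng, mask=brain)

    truth = PhantomTruth(
        L=L, D=D, R=R, t0=t0, k=k, true_acidity=acidity, b0_field=b0,
        label=labels.copy(),
        link={"form": "ACIDITY_MAX*(wL*clip((L-60)/300,0,1)+wD*D+wR*(1-R))",
              "acidity_max": ACIDITY_MAX, "weights": dict(LINK_WEIGHTS),
              "L_norm_range": list(L_NORM_RANGE),
              "link_noise_sd": config.link_noise_sd},
    )

    # DSC volume
    dsc = np.zeros(shape + (config.n_timepoints,))
    curves = simulate_dsc_curve(
        L[brain], D[brain], R[brain], t0[brain], k[brain],
        config.n_timepoints, config.tr_seconds, config.baseline_frames,
        config.noise_sd_dsc, rng,
    )
    dsc[brain] = curves
    bg_level = 10.0
    n_bg = int((~brain).sum())
    dsc[~brain] = bg_level * (
        1.0 + (config.noise_sd_dsc * rng.normal(size=(n_bg, config.n_timepoints))
               if config.noise_sd_dsc > 0 else 0.0)
    )

    # CEST volume
    offsets = offset_schedule()
    sat = np.zeros(shape + (offsets.size,))
    s0 = np.zeros(shape)
    spec, s0_v = simulate_zspectrum(
        acidity[brain], b0[brain], offsets, config.noise_sd_cest, rng
    )
    sat[brain] = spec
    s0[brain] = s0_v

    seg = np.where(np.isin(labels, (LABEL_NC, LABEL_ED, LABEL_ET)), labels, 0).astype(np.int16)
    perfusion = PerfusionSeries(data=dsc, tr_seconds=config.tr_seconds,
                                baseline_frames=config.baseline_frames)
    cest = CestAcquisition(offsets=offsets, saturated=sat, s0=s0, mask=brain)
    return SubjectBundle(
        subject_id=f"sub-{subject_index + 1:02d}", perfusion=perfusion, cest=cest,
        segmentation=seg, brain_mask=brain, truth=truth,
    )


def simulate_cohort(config: PhantomConfig) -> list[SubjectBundle]:
    """All subjects of a cohort, in memory; deterministic given the config."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]


def generate_cohort(config: PhantomConfig, out_dir: Path | str) -> list[Path]:
    """Generate a cohort and write each subject's bundle to ``out_dir``.

    Per subject: ``dsc.nii.gz`` (4D), ``cest.nii.gz`` (4D over offsets),
    ``cest_s0.nii.gz``, ``cest_offsets.txt``, ``seg.nii.gz``,
    ``brain_mask.nii.gz`` and ``truth.npz``; plus a cohort-level
    ``manifest.json`` recording the config and the acidity-link parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subject_dirs: list[Path] = []
    link = None
    for i in range(config.n_subjects):
        bundle = simulate_subject(config, i)
        sdir = out / bundle.subject_id
        try:
            sdir.mkdir(parents=True, exist_ok=True)
            save_nifti(bundle.perfusion.data, sdir / "dsc.nii.gz")
            save_nifti(bundle.cest.saturated, sdir / "cest.nii.gz")
            save_nifti(bundle.cest.s0, sdir / "cest_s0.nii.gz")
            save_offsets(bundle.cest.offsets, sdir / "cest_offsets.txt")
            save_nifti(bundle.segmentation, sdir / "seg.nii.gz", dtype=np.int16)
            save_nifti(bundle.brain_mask, sdir / "brain_mask.nii.gz", dtype=np.uint8)
            np.savez_compressed(sdir / "truth.npz", **bundle.truth.arrays())
        except OSError as exc:
            raise OSError(f"failed writing phantom bundle under {sdir}: {exc}") from exc
        link = bundle.truth.link
        subject_dirs.append(sdir)
    manifest = {
        "config": config.to_dict(),
        "link_function": link,
        "latent_distributions": {
            "tissue_severity_intervals": {str(k): list(v) for k, v in TISSUE_SEVERITY.items()},
            "latent_maps": {k: list(v) for k, v in LATENT_MAPS.items()},
        },
        "k_range": list(K_RANGE),
        "subjects": [d.name for d in subject_dirs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return subject_dirs
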