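"""In-memory containers and NIfTI I/O for perfusion, CEST and segmentation volumes.

All volumes of one subject share a single grid and affine; registration is an
input contract, not something this package performs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: BraTS-style tumor subregion labels used throughout.
LABEL_NC = 1  # necrotic core
LABEL_ED = 2  # peritumoral edema
LABEL_ET = 4  # enhancing tumor
ROI_LABELS = {"NC": LABEL_NC, "ED": LABEL_ED, "ET": LABEL_ET}
ROI_NAMES = {v: k for k, v in ROI_LABELS.items()}

_DEFAULT_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic


@dataclass
class PerfusionSeries:
    """A 4D DSC-MRI signal-time volume (x, y, z, t) with repetition time."""

    data: np.ndarray
    tr_seconds: float
    baseline_frames: int | None = None
    affine: np.ndarray = field(default_factory=lambda: _DEFAULT_AFFINE.copy())

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("PerfusionSeries.data must be 4D (x, y, z, t)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class CestAcquisition:
    """Saturated volumes S(w) indexed by offset frequency plus the reference S0.

    ``saturated`` has shape (x, y, z, n_offsets); ``offsets`` is strictly
    increasing, in ppm from the water resonance.
    """

    offsets: np.ndarray
    saturated: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: _DEFAULT_AFFINE.copy())

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.saturated.ndim != 4 or self.saturated.shape[3] != self.offsets.size:
            raise ValueError("number of saturated volumes must equal number of offsets")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.s0.shape != self.saturated.shape[:3] or self.mask.shape != self.s0.shape:
            raise ValueError("s0/mask grid must match the saturated volumes")
        if np.any(self.s0[self.mask.astype(bool)] <= 0):
            raise ValueError("S0 must be positive inside the mask")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.s0.shape


def save_nifti(data: np.ndarray, path: Path | str, affine: np.ndarray | None = None,
               dtype=np.float32) -> None:
    affine = _DEFAULT_AFFINE if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def load_nifti(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) of a NIfTI file, data as float64."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_offsets(offsets: np.ndarray, path: Path | str) -> None:
    """Sidecar text file: one offset in ppm per line, acquisition order."""
    Path(path).write_text("".join(f"{w:.1f}\n" for w in offsets))


def load_offsets(path: Path | str) -> np.ndarray:
    return np.array([float(line) for line in Path(path).read_text().split()])


def load_cest(cest_path, offsets_path, s0_path, mask_path) -> CestAcquisition:
    sat, affine = load_nifti(cest_path)
    s0, _ = load_nifti(s0_path)
    mask, _ = load_nifti(mask_path)
    return CestAcquisition(offsets=load_offsets(offsets_path), saturated=sat,
                           s0=s0, mask=mask > 0.5, affine=affine)


def load_perfusion(dsc_path, tr_seconds: float,
                   baseline_frames: int | None = None) -> PerfusionSeries:
    data, affine = load_nifti(dsc_path)
    return PerfusionSeries(data=data, tr_seconds=tr_seconds,
                           baseline_frames=baseline_frames, affine=affine)
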