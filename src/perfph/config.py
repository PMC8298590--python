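"""Configuration objects for phantom generation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic multi-subject phantom cohort.

    Noise standard deviations are expressed as fractions of the relevant
    reference signal (DSC: per-voxel baseline; CEST: the unsaturated S0).
    """

    n_subjects: int = 12
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    n_timepoints: int = 60
    tr_seconds: float = 1.5
    baseline_frames: int = 10
    noise_sd_dsc: float = 0.003
    noise_sd_cest: float = 0.005
    b0_amplitude_ppm: float = 0.2
    link_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers, each >= 4")
        if not (0 < self.baseline_frames < self.n_timepoints):
            raise ValueError("need 0 < baseline_frames < n_timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("noise_sd_dsc", "noise_sd_cest", "b0_amplitude_ppm", "link_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class PcaConfig:
    n_components: int = 7
    per_roi_sample: int = 1000
    variance_target: float = 0.99
    bolus_margin: float = 0.05


@dataclass(frozen=True)
class SvrConfig:
    box: float = 1.0
    epsilon: float | None = None  # None -> iqr(targets)/13.49
    subsample: int = 200  # training voxels per ROI per subject


@dataclass(frozen=True)
class CestConfig:
    n_clusters: int = 8
    restrict_to_rois: bool = True  # quantify MTR_asym only where it is consumed


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration; one master seed derives all stage seeds."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    svr: SvrConfig = field(default_factory=SvrConfig)
    cest: CestConfig = field(default_factory=CestConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "phantom": self.phantom.to_dict(),
            "pca": dataclasses.asdict(self.pca),
            "svr": dataclasses.asdict(self.svr),
            "cest": dataclasses.asdict(self.cest),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            phantom=PhantomConfig.from_dict(d.get("phantom", {})) if d.get("phantom") else PhantomConfig(),
            pca=PcaConfig(**d.get("pca", {})),
            svr=SvrConfig(**d.get("svr", {})),
            cest=CestConfig(**d.get("cest", {})),
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
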