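"""Configuration objects for simulation and analysis.

All physical lengths are nanometres.  Axis order everywhere in the package
is ``(z, y, x)``; physical coordinates are nm with the origin at the centre
of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Fixed channel order for the triplex pipeline.
CHANNELS: tuple[str, str, str] = ("INSL5", "PYY", "GLP1")


@dataclass(frozen=True)
class ImagingConfig:
    """Forward-model parameters for synthetic three-channel z-stacks.

    Defaults emulate a reconstructed 3D structured-illumination stack of
    immunolabelled secretory vesicles: ~40 nm lateral pixels, 110 nm
    z-spacing, an anisotropic PSF, and additive Gaussian read noise sized
    so that a unit-amplitude spot has peak SNR ~ 10.
    """

    shape_voxels: tuple[int, int, int] = (16, 128, 128)  # (nz, ny, nx)
    voxel_xy_nm: float = 40.0
    voxel_z_nm: float = 110.0
    psf_sigma_xy_nm: float = 80.0
    psf_sigma_z_nm: float = 150.0
    #: per-channel (z, y, x) translation applied to spot positions, nm
    chromatic_shift_nm: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
    )
    #: additive Gaussian noise SD as a fraction of the maximum spot amplitude
    noise_gaussian_sd: float = 0.1
    #: photons per intensity unit for the optional Poisson stage; 0 disables
    noise_poisson_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape_voxels
        if min(nz, ny, nx) < 1:
            raise ValueError("shape_voxels must be positive")
        for name in ("voxel_xy_nm", "voxel_z_nm", "psf_sigma_xy_nm", "psf_sigma_z_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.chromatic_shift_nm) != 3:
            raise ValueError("chromatic_shift_nm needs one 3-vector per channel")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise levels must be >= 0")
        # a vesicle +/- 3 sigma must fit inside the border margin
        if (
            6 * self.psf_sigma_xy_nm >= (nx - 1) * self.voxel_xy_nm
            or 6 * self.psf_sigma_xy_nm >= (ny - 1) * self.voxel_xy_nm
            or 6 * self.psf_sigma_z_nm >= (nz - 1) * self.voxel_z_nm
        ):
            raise ValueError("volume too small for a vesicle +/-3 sigma inside the border")

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent spanned by voxel centres."""
        nz, ny, nx = self.shape_voxels
        return (
            (nz - 1) * self.voxel_z_nm,
            (ny - 1) * self.voxel_xy_nm,
            (nx - 1) * self.voxel_xy_nm,
        )

    def voxel_sizes_nm(self) -> np.ndarray:
        return np.array([self.voxel_z_nm, self.voxel_xy_nm, self.voxel_xy_nm])


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the vesicle-contents pipeline.

    The defaults are the published operating point: duplicate radius 2 px,
    dim-spot size gate 12 < np < 250 voxels (strict), inter-channel
    prefilter < 200 nm, intensity mask radius 150 nm, positive/empty
    thresholds 0.05/0.02 of the per-channel maximum, and a line-profile
    fit quality gate of R^2 > 0.75.
    """

    dedupe_radius_px: float = 2.0
    np_min: int = 12
    np_max: int = 250
    prefilter_nm: float = 200.0
    mask_radius_nm: float = 150.0
    pos_threshold: float = 0.05
    neg_threshold: float = 0.02
    r2_min: float = 0.75
    #: fit window in voxels as (z, y, x); each entry odd
    fit_window_px: tuple[int, int, int] = (5, 9, 9)
    #: strategy used to split the histogram for bright-spot detection
    bright_mode: str = "multiotsu"
    profile_half_length_px: int = 7

    def __post_init__(self) -> None:
        if self.neg_threshold >= self.pos_threshold:
            raise ValueError("neg_threshold must be < pos_threshold")
        if self.np_min >= self.np_max:
            raise ValueError("np_min must be < np_max")
        for name in ("dedupe_radius_px", "prefilter_nm", "mask_radius_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(w < 1 or w % 2 == 0 for w in self.fit_window_px):
            raise ValueError("fit_window_px entries must be odd and >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "fit_window_px" in raw:
            raw["fit_window_px"] = tuple(raw["fit_window_px"])
        return cls(**raw)
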