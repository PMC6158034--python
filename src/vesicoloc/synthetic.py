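"""Synthetic three-channel vesicle stacks and assay tables with ground truth.

The forward model renders each immunolabelled vesicle as an anisotropic 3D
Gaussian spot (the diffraction-limited image of a sub-resolution granule)
in every channel whose peptide it carries, applies an optional per-channel
chromatic translation, and adds Poisson then Gaussian noise.  Everything is
driven by a single seed so simulated cells are exactly reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import CHANNELS, ImagingConfig
from .stack_io import VoxelGrid, write_stack

#: the seven determinate vesicle content categories, in the fixed order used
#: for multinomial draws
CATEGORY_ORDER: tuple[str, ...] = (
    "single_INSL5",
    "single_PYY",
    "single_GLP1",
    "double_INSL5_PYY",
    "double_INSL5_GLP1",
    "double_PYY_GLP1",
    "triple",
)

CATEGORY_LABELS: dict[str, frozenset[str]] = {
    "single_INSL5": frozenset({"INSL5"}),
    "single_PYY": frozenset({"PYY"}),
    "single_GLP1": frozenset({"GLP1"}),
    "double_INSL5_PYY": frozenset({"INSL5", "PYY"}),
    "double_INSL5_GLP1": frozenset({"INSL5", "GLP1"}),
    "double_PYY_GLP1": frozenset({"PYY", "GLP1"}),
    "triple": frozenset(CHANNELS),
}


def category_fractions(
    single: float = 0.0, double: float = 0.0, triple: float = 1.0
) -> dict[str, float]:
    """Spread aggregate single/double mass uniformly over the sub-categories."""
    out = {c: single / 3 for c in CATEGORY_ORDER[:3]}
    out.update({c: double / 3 for c in CATEGORY_ORDER[3:6]})
    out["triple"] = triple
    return out


@dataclass(frozen=True)
class GroundTruthVesicle:
    """A simulated vesicle's true position, amplitudes and label set."""

    position_nm: tuple[float, float, float]  # (z, y, x)
    amplitudes: tuple[float, float, float]  # per channel, CHANNELS order
    label_set: frozenset[str]

    def __post_init__(self) -> None:
        for ch, amp in zip(CHANNELS, self.amplitudes):
            if (amp > 0) != (ch in self.label_set):
                raise ValueError(
                    f"amplitude/label mismatch for {ch}: amp={amp}, labels={set(self.label_set)}"
                )

    @property
    def category(self) -> str:
        for name, labels in CATEGORY_LABELS.items():
            if labels == self.label_set:
                return name
        raise ValueError(f"unrecognised label set {set(self.label_set)}")


@dataclass
class SyntheticCell:
    """Three rendered channels plus the ground truth that produced them."""

    channels: list[VoxelGrid]
    truth: list[GroundTruthVesicle]
    config: ImagingConfig

    def __post_init__(self) -> None:
        if len(self.channels) != 3 or len({g.shape for g in self.channels}) != 1:
            raise ValueError("SyntheticCell needs 3 channels of identical shape")


def sample_vesicle_field(
    n_vesicles: int,
    fractions: Mapping[str, float],
    min_separation_nm: float,
    rng_seed: int,
    config: ImagingConfig | None = None,
    amplitude: float = 1.0,
    margin_sigma: float = 3.0,
    max_attempts_per_vesicle: int = 2000,
) -> list[GroundTruthVesicle]:
    """Draw vesicle positions and label sets for one simulated cell.

    Category counts are a single multinomial draw (the first variate taken
    from ``default_rng(rng_seed)``, so an external multinomial draw with the
    same seed reproduces them).  Positions are rejection-sampled uniformly
    inside the volume with a ``margin_sigma``-PSF border margin, enforcing a
    pairwise separation of at least ``min_separation_nm``.
    """
    config = config or ImagingConfig()
    probs = np.array([float(fractions.get(c, 0.0)) for c in CATEGORY_ORDER])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"category fractions must sum to 1, got {probs.sum()}")
    rng = np.random.default_rng(rng_seed)
    if n_vesicles == 0:
        return []
    counts = rng.multinomial(n_vesicles, probs)

    margin = margin_sigma * np.array(
        [config.psf_sigma_z_nm, config.psf_sigma_xy_nm, config.psf_sigma_xy_nm]
    )
    hi = np.array(config.extent_nm) - margin
    if np.any(hi <= margin):
        raise ValueError("volume too small for the requested border margin")

    positions: list[np.ndarray] = []
    kept = np.empty((0, 3))
    for _ in range(n_vesicles):
        for attempt in range(max_attempts_per_vesicle):
            cand = rng.uniform(margin, hi)
            if kept.size == 0 or np.min(
                np.linalg.norm(kept - cand, axis=1)
            ) >= min_separation_nm:
                positions.append(cand)
                kept = np.vstack([kept, cand])
                break
        else:
            raise RuntimeError(
                f"could not place vesicle {len(positions) + 1}/{n_vesicles} with "
                f"min separation {min_separation_nm} nm after "
                f"{max_attempts_per_vesicle} attempts; shrink n or the separation"
            )

    vesicles: list[GroundTruthVesicle] = []
    idx = 0
    for cat, cnt in zip(CATEGORY_ORDER, counts):
        labels = CATEGORY_LABELS[cat]
        for _ in range(cnt):
            amps = tuple(amplitude if ch in labels else 0.0 for ch in CHANNELS)
            vesicles.append(
                GroundTruthVesicle(tuple(positions[idx]), amps, labels)
            )
            idx += 1
    return vesicles


def _render_spot(
    canvas: np.ndarray,
    centre_px: np.ndarray,
    sigma_px: np.ndarray,
    amplitude: float,
    cutoff_sigma: float = 4.5,
) -> None:
    """Accumulate one anisotropic Gaussian into ``canvas`` near its centre."""
    lo = np.maximum(np.floor(centre_px - cutoff_sigma * sigma_px).astype(int), 0)
    hi = np.minimum(
        np.ceil(centre_px + cutoff_sigma * sigma_px).astype(int) + 1, canvas.shape
    )
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    arg = (
        (zz - centre_px[0]) ** 2 / (2 * sigma_px[0] ** 2)
        + (yy - centre_px[1]) ** 2 / (2 * sigma_px[1] ** 2)
        + (xx - centre_px[2]) ** 2 / (2 * sigma_px[2] ** 2)
    )
    canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-arg)


def render_stack(
    truth: Sequence[GroundTruthVesicle], config: ImagingConfig
) -> SyntheticCell:
    """Render ground-truth vesicles into a noisy three-channel stack.

    Each vesicle appears in each labelled channel as an anisotropic 3D
    Gaussian centred at its position plus that channel's chromatic shift.
    Noise (optional Poisson stage, then additive Gaussian scaled to the
    maximum amplitude) is added after all spots are summed; negative
    values are clipped to zero.
    """
    rng = np.random.default_rng(config.seed)
    voxel = config.voxel_sizes_nm()
    sigma_px = (
        np.array([config.psf_sigma_z_nm, config.psf_sigma_xy_nm, config.psf_sigma_xy_nm])
        / voxel
    )
    max_amp = max((max(v.amplitudes) for v in truth), default=1.0) or 1.0

    grids = []
    for ci, ch in enumerate(CHANNELS):
        canvas = np.zeros(config.shape_voxels)
        shift = np.asarray(config.chromatic_shift_nm[ci])
        for v in truth:
            if v.amplitudes[ci] <= 0:
                continue
            centre_px = (np.asarray(v.position_nm) + shift) / voxel
            _render_spot(canvas, centre_px, sigma_px, v.amplitudes[ci])
        if config.noise_poisson_scale > 0:
            canvas = rng.poisson(canvas * config.noise_poisson_scale) / (
                config.noise_poisson_scale
            )
        if config.noise_gaussian_sd > 0:
            canvas = canvas + rng.normal(
                0.0, config.noise_gaussian_sd * max_amp, size=canvas.shape
            )
        np.clip(canvas, 0.0, None, out=canvas)
        grids.append(
            VoxelGrid(canvas, config.voxel_xy_nm, config.voxel_z_nm, channel_name=ch)
        )
    return SyntheticCell(grids, list(truth), config)


def write_synthetic_cell(cell: SyntheticCell, out_dir: str | Path, stem: str = "cell") -> dict[str, Path]:
    """Write the stack as OME-TIFF and the ground truth as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff = write_stack(out_dir / f"{stem}.ome.tiff", cell.channels)
    truth_path = out_dir / f"{stem}_truth.csv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["vesicle_id", "z_nm", "y_nm", "x_nm", "amp_insl5", "amp_pyy", "amp_glp1", "label_set"]
        )
        for i, v in enumerate(cell.truth):
            w.writerow(
                [i, *[f"{p:.6f}" for p in v.position_nm], *v.amplitudes,
                 "+".join(ch for ch in CHANNELS if ch in v.label_set)]
            )
    return {"stack": tiff, "truth": truth_path}


# ---------------------------------------------------------------------------
# synthetic secretion tables

@dataclass(frozen=True)
class SecretionRecord:
    """One well's LC-MS peak area for one hormone."""

    culture_id: str
    condition: str
    hormone: str
    peak_area: float
    protein_mg: float
    replicate: int = 0


#: arbitrary per-hormone LC-MS response factors (peak area per unit secretion)
DEFAULT_HORMONE_SCALES: dict[str, float] = {"INSL5": 1.0, "PYY": 5.0, "GLP1": 3.0}


def make_secretion_table(
    conditions: Mapping[str, float],
    n_cultures: int,
    noise_cv: float,
    rng_seed: int,
    control_label: str = "control",
    duplicates: int = 2,
    hormone_scales: Mapping[str, float] | None = None,
    shared_fraction: float = 0.75,
) -> list[SecretionRecord]:
    """Simulate per-culture hormone secretion wells under a latent stimulus.

    ``conditions`` maps condition label to its latent effect size (control
    should be 1).  Every culture gets ``duplicates`` wells per condition; a
    well's peak area is protein content x condition effect x hormone scale
    x mean-one log-normal noise with total coefficient of variation
    ``noise_cv``.  A ``shared_fraction`` of the noise log-variance is a
    latent per-well stimulus strength common to all three hormones (a well
    that responds strongly does so for every peptide); the rest is
    independent per-hormone measurement noise.  The shared component makes
    fold changes positively correlated across hormones.
    """
    if control_label not in conditions:
        raise ValueError(f"conditions must include the control label {control_label!r}")
    if any(e < 0 for e in conditions.values()):
        raise ValueError("effect sizes must be >= 0")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    scales = dict(hormone_scales or DEFAULT_HORMONE_SCALES)
    rng = np.random.default_rng(rng_seed)
    # mean-one lognormal multipliers; log-variance split shared vs per-hormone
    sig2 = float(np.log1p(noise_cv**2))
    sig_shared = np.sqrt(shared_fraction * sig2)
    sig_horm = np.sqrt((1.0 - shared_fraction) * sig2)
    records: list[SecretionRecord] = []
    for c in range(n_cultures):
        culture = f"culture{c + 1}"
        for cond, effect in conditions.items():
            for rep in range(duplicates):
                protein = float(rng.lognormal(np.log(0.15), 0.2))
                latent = (
                    float(rng.lognormal(-0.5 * sig_shared**2, sig_shared))
                    if sig_shared > 0
                    else 1.0
                )
                for hormone in CHANNELS:
                    noise = (
                        float(rng.lognormal(-0.5 * sig_horm**2, sig_horm))
                        if sig_horm > 0
                        else 1.0
                    )
                    records.append(
                        SecretionRecord(
                            culture_id=culture,
                            condition=cond,
                            hormone=hormone,
                            peak_area=protein * effect * scales[hormone] * latent * noise,
                            protein_mg=protein,
                            replicate=rep,
                        )
                    )
    return records
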