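"""Candidate vesicle detection per channel and cross-channel merging.

Two complementary detectors: a histogram-split detector for bright spots
(three-class Otsu, top class) and a dim-spot detector (binary Otsu with a
strict 12 < np < 250 voxel-count gate on connected components).  Components
use 26-connectivity in 3D.  Candidates from all channels are pooled and
de-duplicated with a brighter-wins greedy merge at a 2-pixel radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .stack_io import VoxelGrid

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class CandidateSpot:
    voxel_index: tuple[int, int, int]  # (z, y, x)
    channel_name: str
    mode: str  # "bright" | "dim"
    peak_intensity: float


def _components_to_spots(
    grid: VoxelGrid, mask: np.ndarray, mode: str, np_min: int | None = None,
    np_max: int | None = None, min_size: int = 1,
) -> list[CandidateSpot]:
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(grid.data, labels, index=range(1, n + 1))
    peaks = ndimage.maximum(grid.data, labels, index=range(1, n + 1))
    spots = []
    for size, com, peak in zip(sizes, centroids, peaks):
        if size < min_size:
            continue
        if np_min is not None and not (np_min < size < np_max):
            continue
        idx = tuple(int(round(c)) for c in com)
        idx = tuple(np.clip(idx, 0, np.array(grid.shape) - 1))
        spots.append(CandidateSpot(idx, grid.channel_name, mode, float(peak)))
    return spots


def detect_bright(grid: VoxelGrid, min_size: int = 5) -> list[CandidateSpot]:
    """Detect bright spots by splitting the intensity histogram.

    The histogram is split into three classes with multi-level Otsu; voxels
    in the top class form the bright mask.  Returns the component centroids
    rounded to the nearest voxel.  Components smaller than ``min_size``
    voxels are dropped: a diffraction-limited spot spans the PSF core
    (several voxels at these voxel sizes), so tiny supra-threshold
    clusters are noise spikes, not vesicles.  A (near-)constant image
    yields no spots.
    """
    data = grid.data
    if np.ptp(data) == 0:
        return []
    try:
        thresholds = threshold_multiotsu(data, classes=3)
    except ValueError:  # fewer distinct values than classes
        return []
    mask = data > thresholds[-1]
    return _components_to_spots(grid, mask, mode="bright", min_size=min_size)


def detect_dim(grid: VoxelGrid, np_min: int = 12, np_max: int = 250) -> list[CandidateSpot]:
    """Detect dim spots: binary Otsu then a strict voxel-count gate.

    Components of the Otsu-positive mask are kept iff their voxel count np
    satisfies np_min < np < np_max (both bounds strict).
    """
    if np_min >= np_max:
        raise ValueError("np_min must be < np_max")
    data = grid.data
    if np.ptp(data) == 0:
        return []
    mask = data > threshold_otsu(data)
    return _components_to_spots(grid, mask, mode="dim", np_min=np_min, np_max=np_max)


def _scaled_distance_px(
    a: np.ndarray, b: np.ndarray, z_scale: float
) -> np.ndarray:
    """Distance in xy-pixel units; z index differences scaled by anisotropy."""
    d = a - b
    d = d * np.array([z_scale, 1.0, 1.0])
    return np.sqrt((d**2).sum(axis=-1))


def merge_candidates(
    per_channel: Sequence[Sequence[CandidateSpot]],
    dedupe_radius_px: float = 2.0,
    voxel_xy_nm: float = 40.0,
    voxel_z_nm: float = 110.0,
) -> list[CandidateSpot]:
    """Pool candidates across channels and remove duplicates.

    Greedy in descending peak intensity: a candidate within
    ``dedupe_radius_px`` (xy-pixel units, z scaled by the voxel anisotropy)
    of an already-kept candidate is absorbed by it, so the brighter of any
    duplicate pair survives.  The output is duplicate-free under the same
    rule.
    """
    pool = [s for spots in per_channel for s in spots]
    pool.sort(key=lambda s: (-s.peak_intensity, s.voxel_index))
    z_scale = voxel_z_nm / voxel_xy_nm
    kept: list[CandidateSpot] = []
    kept_idx = np.empty((0, 3))
    for spot in pool:
        idx = np.asarray(spot.voxel_index, dtype=float)
        if kept_idx.size and np.min(
            _scaled_distance_px(kept_idx, idx, z_scale)
        ) <= dedupe_radius_px:
            continue
        kept.append(spot)
        kept_idx = np.vstack([kept_idx, idx])
    return kept


def detect_all(
    channels: Sequence[VoxelGrid],
    np_min: int = 12,
    np_max: int = 250,
    dedupe_radius_px: float = 2.0,
) -> list[CandidateSpot]:
    """Run both detectors on every channel and merge the candidate pool."""
    per_channel = []
    for grid in channels:
        per_channel.append(detect_bright(grid))
        per_channel.append(detect_dim(grid, np_min=np_min, np_max=np_max))
    g0 = channels[0]
    return merge_candidates(
        per_channel,
        dedupe_radius_px=dedupe_radius_px,
        voxel_xy_nm=g0.voxel_xy_nm,
        voxel_z_nm=g0.voxel_z_nm,
    )
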