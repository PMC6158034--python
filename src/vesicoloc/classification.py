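"""Inter-channel prefilter, vesicle intensity measurement and peptide calls.

A vesicle passes the prefilter iff its three per-channel positions are
pairwise closer than 200 nm (a larger separation suggests a neighbouring
vesicle was detected in one channel).  Intensities are measured on images
normalised to their per-channel maximum, as the mean over a 150 nm
spherical mask minus the per-channel mean-of-volume background.  A channel
is called positive above 0.05, empty below 0.02, and indeterminate in the
dead band between (including exact threshold equality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import CHANNELS, AnalysisConfig
from .localization import LocalizedSpot
from .stack_io import VoxelGrid

SINGLE_CATEGORIES = {
    "INSL5": "single_INSL5",
    "PYY": "single_PYY",
    "GLP1": "single_GLP1",
}
DOUBLE_CATEGORIES = {
    frozenset({"INSL5", "PYY"}): "double_INSL5_PYY",
    frozenset({"INSL5", "GLP1"}): "double_INSL5_GLP1",
    frozenset({"PYY", "GLP1"}): "double_PYY_GLP1",
}


@dataclass
class VesicleRecord:
    """One vesicle's positions, normalized intensities, calls and category."""

    vesicle_id: int
    positions_nm: np.ndarray  # (3, 3)
    norm_intensity: tuple[float, float, float]
    call: tuple[str, str, str]  # positive | negative | indeterminate
    prefilter_pass: bool
    category: str


@dataclass
class CellSummary:
    """Per-cell category counts and percentages (the per-cell figure row)."""

    cell_id: str
    n_detected: int
    n_prefilter_pass: int
    n_single: int
    n_double: int
    n_triple: int
    n_indeterminate: int
    pct_single: float  # NaN when no determinate vesicles
    pct_double: float
    pct_triple: float

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        for k in ("pct_single", "pct_double", "pct_triple"):
            if np.isnan(out[k]):
                out[k] = None
        return out


def prefilter_by_separation(
    spots: Sequence[LocalizedSpot], prefilter_nm: float = 200.0
) -> np.ndarray:
    """Flag spots whose three channel positions all lie < prefilter_nm apart."""
    flags = np.empty(len(spots), dtype=bool)
    for i, s in enumerate(spots):
        p = s.positions_nm
        d01 = np.linalg.norm(p[0] - p[1])
        d02 = np.linalg.norm(p[0] - p[2])
        d12 = np.linalg.norm(p[1] - p[2])
        flags[i] = max(d01, d02, d12) < prefilter_nm
    return flags


class ChannelNormalization:
    """Per-channel max-normalization and mean-of-volume background.

    Computed once per channel per image; both the maximum and the
    background are properties of the full 3D volume.
    """

    def __init__(self, grid: VoxelGrid):
        peak = float(grid.data.max())
        if peak <= 0:
            raise ValueError(f"channel {grid.channel_name}: all-zero volume")
        self.grid = grid
        self.peak = peak
        self.normalized = grid.data / peak
        self.background = float(self.normalized.mean())


def _sphere_offsets(grid: VoxelGrid, mask_radius_nm: float) -> np.ndarray:
    voxel = grid.voxel_sizes_nm()
    half = np.floor(mask_radius_nm / voxel).astype(int) + 1
    zz, yy, xx = np.mgrid[-half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1]
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)


def measure_intensity(
    norm: ChannelNormalization,
    centre_nm: Sequence[float],
    mask_radius_nm: float = 150.0,
) -> float:
    """Background-subtracted mean normalized intensity in a spherical mask.

    The mask is the set of voxels whose centres lie within
    ``mask_radius_nm`` of ``centre_nm`` (true physical sphere; anisotropic
    voxels handled by working in nm).  May be negative for empty channels.
    """
    grid = norm.grid
    voxel = grid.voxel_sizes_nm()
    centre = np.asarray(centre_nm, dtype=float)
    base = np.round(centre / voxel).astype(int)
    idx = base + _sphere_offsets(grid, mask_radius_nm)
    inside = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
    idx = idx[inside]
    dist = np.linalg.norm(idx * voxel - centre, axis=1)
    idx = idx[dist <= mask_radius_nm]
    if len(idx) == 0:
        raise ValueError(
            "spherical mask contains no voxel centres; increase mask_radius_nm "
            "or use finer voxels"
        )
    vals = norm.normalized[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(vals.mean() - norm.background)


def classify_vesicle(
    intensities: Sequence[float],
    pos_threshold: float = 0.05,
    neg_threshold: float = 0.02,
) -> tuple[tuple[str, str, str], str]:
    """Per-channel peptide calls and the resulting content category.

    Strictly above ``pos_threshold`` -> positive (contains the peptide);
    strictly below ``neg_threshold`` -> negative (empty); anything in the
    dead band -> indeterminate, which makes the whole vesicle
    indeterminate.
    """
    if neg_threshold >= pos_threshold:
        raise ValueError("neg_threshold must be < pos_threshold")
    calls = tuple(
        "positive" if v > pos_threshold else ("negative" if v < neg_threshold else "indeterminate")
        for v in intensities
    )
    if any(c == "indeterminate" for c in calls):
        return calls, "indeterminate"
    positive = frozenset(ch for ch, c in zip(CHANNELS, calls) if c == "positive")
    if len(positive) == 3:
        category = "triple"
    elif len(positive) == 2:
        category = DOUBLE_CATEGORIES[positive]
    elif len(positive) == 1:
        category = SINGLE_CATEGORIES[next(iter(positive))]
    else:
        category = "indeterminate"  # all empty: no content call possible
    return calls, category


def classify_spots(
    channels: Sequence[VoxelGrid],
    spots: Sequence[LocalizedSpot],
    config: AnalysisConfig | None = None,
) -> list[VesicleRecord]:
    """Prefilter, measure and classify a full set of localized spots."""
    config = config or AnalysisConfig()
    norms = [ChannelNormalization(g) for g in channels]
    flags = prefilter_by_separation(spots, config.prefilter_nm)
    extent = np.array(channels[0].shape) * channels[0].voxel_sizes_nm()
    records = []
    for s, passed in zip(spots, flags):
        if not passed:
            # excluded vesicles get no intensity measurement
            records.append(
                VesicleRecord(
                    vesicle_id=s.vesicle_id,
                    positions_nm=s.positions_nm.copy(),
                    norm_intensity=(float("nan"),) * 3,
                    call=("indeterminate",) * 3,
                    prefilter_pass=False,
                    category="excluded",
                )
            )
            continue
        intensities = tuple(
            measure_intensity(norms[c], s.positions_nm[c], config.mask_radius_nm)
            if np.all(s.positions_nm[c] >= 0) and np.all(s.positions_nm[c] < extent)
            else float("nan")
            for c in range(3)
        )
        if np.any(np.isnan(intensities)):
            calls, category = (
                tuple("indeterminate" if np.isnan(v) else c for v, c in zip(
                    intensities, classify_vesicle(
                        np.nan_to_num(intensities), config.pos_threshold, config.neg_threshold
                    )[0]
                )),
                "indeterminate",
            )
        else:
            calls, category = classify_vesicle(
                intensities, config.pos_threshold, config.neg_threshold
            )
        records.append(
            VesicleRecord(
                vesicle_id=s.vesicle_id,
                positions_nm=s.positions_nm.copy(),
                norm_intensity=intensities,
                call=calls,
                prefilter_pass=True,
                category=category,
            )
        )
    return records


def summarize_cell(records: Sequence[VesicleRecord], cell_id: str = "") -> CellSummary:
    """Count and percentage vesicle content categories for one cell.

    Percentages are over determinate prefilter-passing vesicles; with none,
    they are reported as NaN (counts are still emitted).
    """
    n_detected = len(records)
    n_pass = sum(r.prefilter_pass for r in records)
    n_single = sum(r.category.startswith("single_") for r in records)
    n_double = sum(r.category.startswith("double_") for r in records)
    n_triple = sum(r.category == "triple" for r in records)
    n_indet = sum(r.category == "indeterminate" for r in records)
    n_det = n_single + n_double + n_triple
    if n_det > 0:
        pct = (100.0 * n_single / n_det, 100.0 * n_double / n_det, 100.0 * n_triple / n_det)
    else:
        pct = (float("nan"),) * 3
    return CellSummary(
        cell_id=cell_id,
        n_detected=n_detected,
        n_prefilter_pass=n_pass,
        n_single=n_single,
        n_double=n_double,
        n_triple=n_triple,
        n_indeterminate=n_indet,
        pct_single=pct[0],
        pct_double=pct[1],
        pct_triple=pct[2],
    )


def prefilter_pass_rates_by_category(
    records: Sequence[VesicleRecord], truth_categories: Sequence[str]
) -> dict[str, float]:
    """Prefilter pass rate per true category (single/double/triple).

    A diagnostic for bias of the separation prefilter against sparser
    label sets; no significance test is attached.
    """
    buckets: dict[str, list[bool]] = {"single": [], "double": [], "triple": []}
    for r, cat in zip(records, truth_categories):
        key = "triple" if cat == "triple" else cat.split("_")[0]
        buckets[key].append(r.prefilter_pass)
    return {
        k: (100.0 * float(np.mean(v)) if v else float("nan"))
        for k, v in buckets.items()
    }
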