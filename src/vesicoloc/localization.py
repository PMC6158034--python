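"""Sub-pixel spot localization and chromatic registration.

Each merged candidate is refined independently in every channel by
least-squares fitting of an anisotropic axis-aligned 3D Gaussian plus a
constant offset over a local window; candidates whose windows overlap are
fitted jointly as a sum of Gaussians sharing one offset (the "mixture").
Chromatic aberration is then removed by translating channels so their mean
spot positions coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import CHANNELS
from .detection import CandidateSpot
from .stack_io import VoxelGrid

SIGMA_BOUNDS_PX = (0.5, 10.0)  # keeps fits away from delta spikes and flats
MAX_ITER = 200


@dataclass
class FittedSpot:
    """One seed's fit result in one channel (positions in nm)."""

    position_nm: np.ndarray  # (z, y, x)
    amplitude: float
    sigma_nm: tuple[float, float]  # (sigma_xy, sigma_z)
    converged: bool


@dataclass
class LocalizedSpot:
    """Per-channel sub-pixel positions for one vesicle."""

    vesicle_id: int
    positions_nm: np.ndarray  # (3 channels, 3) in (z, y, x)
    fit_amplitude: np.ndarray  # (3,)
    fit_sigma_nm: np.ndarray  # (3, 2) as (sigma_xy, sigma_z)
    fit_converged: np.ndarray  # (3,) bool


def _window_bounds(
    seed: tuple[int, int, int], half: np.ndarray, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    lo = np.maximum(np.asarray(seed) - half, 0)
    hi = np.minimum(np.asarray(seed) + half + 1, shape)
    return lo, hi


def _overlapping_neighbours(
    los: np.ndarray, his: np.ndarray, i: int, max_neighbours: int
) -> list[int]:
    """Indices of the seeds whose windows overlap seed i's window.

    Capped at the ``max_neighbours`` nearest (by window centre) so that a
    dense field never produces an unbounded joint fit.
    """
    overlap = np.all((los[i] < his) & (los < his[i]), axis=1)
    overlap[i] = False
    js = np.nonzero(overlap)[0]
    if len(js) > max_neighbours:
        centres = (los + his) / 2.0
        d = np.linalg.norm(centres[js] - centres[i], axis=1)
        js = js[np.argsort(d)[:max_neighbours]]
    return [int(j) for j in js]


def _model_and_jac(params: np.ndarray, coords: tuple, n_spots: int):
    """Sum-of-Gaussians + offset model and its Jacobian on flattened coords."""
    zz, yy, xx = coords
    m = np.full(zz.shape, params[-1])
    jac = np.empty(zz.shape + (6 * n_spots + 1,))
    jac[..., -1] = 1.0
    for s in range(n_spots):
        amp, z0, y0, x0, sxy, sz = params[6 * s : 6 * s + 6]
        dz, dy, dx = zz - z0, yy - y0, xx - x0
        r2 = dy**2 + dx**2
        g = np.exp(-r2 / (2 * sxy**2) - dz**2 / (2 * sz**2))
        m += amp * g
        ag = amp * g
        jac[..., 6 * s + 0] = g
        jac[..., 6 * s + 1] = ag * dz / sz**2
        jac[..., 6 * s + 2] = ag * dy / sxy**2
        jac[..., 6 * s + 3] = ag * dx / sxy**2
        jac[..., 6 * s + 4] = ag * r2 / sxy**3
        jac[..., 6 * s + 5] = ag * dz**2 / sz**3
    return m, jac


def _centroid_fallback(
    grid: VoxelGrid, seed: tuple[int, int, int], half: np.ndarray
) -> FittedSpot:
    lo, hi = _window_bounds(seed, half, grid.shape)
    win = grid.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    total = win.sum()
    if total <= 0:
        centre_px = np.asarray(seed, dtype=float)
    else:
        zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        centre_px = np.array(
            [(c * win).sum() / total for c in (zz, yy, xx)]
        )
    pos_nm = centre_px * grid.voxel_sizes_nm()
    return FittedSpot(pos_nm, float(win.max(initial=0.0)), (np.nan, np.nan), False)


def fit_centres(
    grid: VoxelGrid,
    seeds: Sequence[CandidateSpot | tuple[int, int, int]],
    fit_window_px: tuple[int, int, int] = (5, 9, 9),
    max_neighbours: int = 4,
) -> list[FittedSpot]:
    """Refine seed positions to sub-pixel accuracy in one channel.

    Each seed is fitted over the union of its window with those of its
    directly overlapping neighbours, as a sum of Gaussians (one per seed in
    that neighbourhood) sharing a constant offset; only the focal seed's
    parameters are kept, so every fit stays small no matter how dense the
    field.  A seed whose fit fails (or whose window is all zero) falls back
    to the intensity-weighted centroid of its window with
    ``converged=False``.
    """
    idxs = [
        tuple(s.voxel_index) if isinstance(s, CandidateSpot) else tuple(s)
        for s in seeds
    ]
    if not idxs:
        return []
    half = np.asarray(fit_window_px) // 2
    voxel = grid.voxel_sizes_nm()
    bounds = [_window_bounds(i, half, grid.shape) for i in idxs]
    los = np.array([b[0] for b in bounds])
    his = np.array([b[1] for b in bounds])

    results: list[FittedSpot] = []
    for i in range(len(idxs)):
        group = [i] + _overlapping_neighbours(los, his, i, max_neighbours)
        glo = los[group].min(axis=0)
        ghi = his[group].max(axis=0)
        win = grid.data[glo[0] : ghi[0], glo[1] : ghi[1], glo[2] : ghi[2]]
        if win.max(initial=0.0) <= 0:
            results.append(_centroid_fallback(grid, idxs[i], half))
            continue
        zz, yy, xx = np.mgrid[glo[0] : ghi[0], glo[1] : ghi[1], glo[2] : ghi[2]]
        coords = (
            zz.ravel().astype(float),
            yy.ravel().astype(float),
            xx.ravel().astype(float),
        )
        y_obs = win.ravel()
        offset0 = float(np.percentile(y_obs, 25))

        n_spots = len(group)
        # a fitted centre is a refinement of its detected centroid: keep it
        # within ~2 px of the seed so the fit cannot latch onto a
        # neighbouring spot at the window edge
        travel = np.minimum(half, [1.5, 2.0, 2.0])
        p0, lb, ub = [], [], []
        for j in group:
            seed = np.asarray(idxs[j], dtype=float)
            amp0 = max(float(grid.data[idxs[j]]) - offset0, 1e-6)
            p0 += [amp0, *seed, 2.0, 1.5]
            lb += [0.0, *(seed - travel), SIGMA_BOUNDS_PX[0], SIGMA_BOUNDS_PX[0]]
            ub += [np.inf, *(seed + travel), SIGMA_BOUNDS_PX[1], SIGMA_BOUNDS_PX[1]]
        p0 += [offset0]
        lb += [-np.inf]
        ub += [np.inf]

        # fun and jac share one forward evaluation via a one-entry cache
        cache: dict = {"key": None, "m": None, "j": None}

        def _eval(p):
            key = p.tobytes()
            if cache["key"] != key:
                m, j = _model_and_jac(p, coords, n_spots)
                cache.update(key=key, m=m, j=j)
            return cache["m"], cache["j"]

        def residual(p):
            return _eval(p)[0] - y_obs

        def jac(p):
            return _eval(p)[1]

        try:
            res = least_squares(
                residual,
                np.asarray(p0),
                jac=jac,
                bounds=(np.asarray(lb), np.asarray(ub)),
                method="trf",
                ftol=1e-8,
                xtol=1e-6,  # px units: ~4e-5 nm, far below localization noise
                max_nfev=MAX_ITER,
            )
            ok = res.success or res.status > 0
        except Exception:
            ok = False
            res = None
        amp = res.x[0] if ok else -1.0
        if ok:
            # a fitted amplitude must clear the local noise floor, or the
            # "spot" is a noise bump and its sub-pixel position meaningless
            noise_sd = float(np.std(res.fun))
            if amp <= max(3.0 * noise_sd, 0.0):
                ok = False
        if not ok or amp <= 0:
            results.append(_centroid_fallback(grid, idxs[i], half))
            continue
        _, z0, y0, x0, sxy, sz = res.x[:6]
        results.append(
            FittedSpot(
                np.array([z0, y0, x0]) * voxel,
                float(amp),
                (float(sxy * grid.voxel_xy_nm), float(sz * grid.voxel_z_nm)),
                True,
            )
        )
    return results


def localize_spots(
    channels: Sequence[VoxelGrid],
    candidates: Sequence[CandidateSpot],
    fit_window_px: tuple[int, int, int] = (5, 9, 9),
) -> list[LocalizedSpot]:
    """Fit every merged candidate independently in each channel."""
    per_channel = [fit_centres(g, candidates, fit_window_px) for g in channels]
    spots = []
    for i in range(len(candidates)):
        fits = [per_channel[c][i] for c in range(len(channels))]
        spots.append(
            LocalizedSpot(
                vesicle_id=i,
                positions_nm=np.array([f.position_nm for f in fits]),
                fit_amplitude=np.array([f.amplitude for f in fits]),
                fit_sigma_nm=np.array([f.sigma_nm for f in fits]),
                fit_converged=np.array([f.converged for f in fits]),
            )
        )
    return spots


def dedupe_spots(
    spots: Sequence[LocalizedSpot],
    dedupe_radius_px: float = 2.0,
    voxel_xy_nm: float = 40.0,
) -> list[LocalizedSpot]:
    """Re-apply the coordinate-duplicate rule to refined positions.

    Two detection-stage candidates of one vesicle (e.g. from different
    channels under chromatic shift) can sit just beyond the dedupe radius
    yet converge to the same sub-pixel centre; after refinement they are
    duplicates under the same within-2-pixels rule.  The brighter fit
    survives.  Distances use the mean per-spot position across channels,
    in nm (the pixel rule times the xy pixel size).
    """
    radius_nm = dedupe_radius_px * voxel_xy_nm
    order = sorted(
        range(len(spots)), key=lambda i: -float(np.max(spots[i].fit_amplitude))
    )
    kept: list[int] = []
    centres = np.array([s.positions_nm.mean(axis=0) for s in spots])
    for i in order:
        if kept and np.min(
            np.linalg.norm(centres[kept] - centres[i], axis=1)
        ) <= radius_nm:
            continue
        kept.append(i)
    kept.sort()
    return [spots[i] for i in kept]


def estimate_channel_offsets(spots: Sequence[LocalizedSpot]) -> np.ndarray:
    """Per-channel mean-position offsets relative to channel 0.

    Means are taken over the spots with converged fits in *all* channels:
    on a common vesicle set the spatial scatter of vesicle positions is
    shared between channels and cancels in the difference of means,
    leaving only the chromatic offset.  Disjoint per-channel sets would
    re-introduce that scatter (hundreds of nm) into the estimate.
    """
    for c in range(3):
        if not any(s.fit_converged[c] for s in spots):
            raise ValueError(
                f"channel {CHANNELS[c]} has no converged localizations; "
                "relax detection before registering"
            )
    common = [s for s in spots if bool(np.all(s.fit_converged[:3]))]
    if not common:
        raise ValueError(
            "no spot converged in all three channels; relax detection "
            "before registering"
        )
    means = np.stack([s.positions_nm[:3] for s in common]).mean(axis=0)
    return means - means[0]


def register_channels(
    spots: Sequence[LocalizedSpot],
) -> tuple[list[LocalizedSpot], np.ndarray]:
    """Translate channels so their mean spot positions coincide.

    Returns the registered spots and the (3, 3) per-channel corrections
    that were subtracted (channel 0's correction is zero).  After the call
    the per-channel means over converged spots agree to < 1e-9 nm.
    """
    offsets = estimate_channel_offsets(spots)
    out = []
    for s in spots:
        out.append(
            LocalizedSpot(
                vesicle_id=s.vesicle_id,
                positions_nm=s.positions_nm - offsets,
                fit_amplitude=s.fit_amplitude.copy(),
                fit_sigma_nm=s.fit_sigma_nm.copy(),
                fit_converged=s.fit_converged.copy(),
            )
        )
    return out, offsets
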