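"""Bright/dim spot detectors and the cross-channel duplicate merge."""

from collections import deque

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import vesicoloc as v
from vesicoloc.detection import CandidateSpot, merge_candidates
from vesicoloc.stack_io import VoxelGrid


def _grid(data, xy=40.0, z=110.0, name="INSL5"):
    return VoxelGrid(np.asarray(data, float), xy, z, name)


# -- independent oracle: histogram Otsu + BFS flood fill, no skimage/scipy --

def _otsu_bruteforce(data, nbins=256):
    """Maximize between-class variance by explicit loop over split points.

    The threshold is reported as the bin centre of the last lower-class
    bin (the usual convention, so borderline voxels classify the same way
    under `value > threshold`).
    """
    counts, edges = np.histogram(data.ravel(), bins=nbins)
    total = counts.sum()
    mids = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, mids[0]
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * mids[:k]).sum() / w0
        m1 = (counts[k:] * mids[k:]).sum() / w1
        between = w0 / total * w1 / total * (m0 - m1) ** 2
        if between > best:
            best, best_t = between, mids[k - 1]
    return best_t


def _flood_fill_components(mask):
    """26-connected components by BFS."""
    visited = np.zeros_like(mask, dtype=bool)
    comps = []
    nz, ny, nx = mask.shape
    for start in zip(*np.nonzero(mask & ~visited)):
        if visited[start]:
            continue
        comp = []
        queue = deque([start])
        visited[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.append((z, y, x))
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        q = (z + dz, y + dy, x + dx)
                        if (
                            0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx
                            and mask[q] and not visited[q]
                        ):
                            visited[q] = True
                            queue.append(q)
        comps.append(comp)
    return comps


def _detect_dim_oracle(grid, np_min=12, np_max=250):
    if np.ptp(grid.data) == 0:
        return set()
    mask = grid.data > _otsu_bruteforce(grid.data)
    out = set()
    for comp in _flood_fill_components(mask):
        if not (np_min < len(comp) < np_max):
            continue
        w = np.array([grid.data[c] for c in comp])
        com = (np.array(comp) * w[:, None]).sum(axis=0) / w.sum()
        out.add(tuple(int(round(c)) for c in com))
    return out


class TestDetectBright:
    def test_all_zero_volume(self):
        assert v.detect_bright(_grid(np.zeros((4, 16, 16)))) == []

    def test_single_spot_at_argmax(self, quiet_config):
        truth = v.sample_vesicle_field(1, {"triple": 1.0}, 400.0, 3, quiet_config)
        cell = v.render_stack(truth, quiet_config)
        g = cell.channels[0]
        spots = v.detect_bright(g)
        assert len(spots) == 1
        assert spots[0].voxel_index == np.unravel_index(np.argmax(g.data), g.shape)
        assert spots[0].mode == "bright"

    def test_two_separated_spots(self, quiet_config):
        truth = v.sample_vesicle_field(2, {"triple": 1.0}, 1200.0, 8, quiet_config)
        cell = v.render_stack(truth, quiet_config)
        g = cell.channels[0]
        spots = v.detect_bright(g)
        assert len(spots) == 2
        # each candidate must sit at the argmax of its own neighbourhood
        for s in spots:
            zc, yc, xc = s.voxel_index
            sl = (
                slice(max(zc - 3, 0), zc + 4),
                slice(max(yc - 5, 0), yc + 6),
                slice(max(xc - 5, 0), xc + 6),
            )
            local = g.data[sl]
            assert g.data[s.voxel_index] == local.max()


class TestDetectDim:
    @pytest.mark.parametrize(
        "n_voxels,expected", [(12, 0), (13, 1), (250, 0), (249, 1)]
    )
    def test_voxel_count_gate_is_strict(self, n_voxels, expected):
        # one rectangular blob of exactly n_voxels bright voxels on a dark field
        data = np.zeros((8, 32, 32))
        flat = np.zeros(n_voxels, dtype=int)
        # fill a 1 x ny x nx box plus remainder in the next row
        ny = n_voxels // 16
        data[3, 8 : 8 + ny, 8:24] = 1.0
        rem = n_voxels - ny * 16
        if rem:
            data[3, 8 + ny, 8 : 8 + rem] = 1.0
        assert int(data.sum()) == n_voxels
        spots = v.detect_dim(_grid(data), 12, 250)
        assert len(spots) == expected

    def test_constant_image(self):
        assert v.detect_dim(_grid(np.ones((4, 16, 16)))) == []

    def test_matches_bruteforce_oracle_on_random_volumes(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            raw = gaussian_filter(rng.random((32, 32, 32)), sigma=1.5)
            g = _grid(raw)
            ours = {s.voxel_index for s in v.detect_dim(g)}
            assert ours == _detect_dim_oracle(g)


class TestMergeCandidates:
    def _spot(self, idx, peak, name="INSL5"):
        return CandidateSpot(tuple(idx), name, "bright", peak)

    def test_pair_within_radius_keeps_brighter(self):
        a = self._spot((5, 10, 10), 2.0)
        b = self._spot((5, 10, 12), 1.0)  # 2.0 px apart -> within "<= 2 px"
        kept = merge_candidates([[a], [b]], dedupe_radius_px=2.0)
        assert kept == [a]
        c = self._spot((5, 11, 11), 1.5)  # sqrt(2) ~ 1.41 px from a
        kept = merge_candidates([[a], [c]], dedupe_radius_px=2.0)
        assert kept == [a]

    def test_pair_beyond_radius_survives(self):
        a = self._spot((5, 10, 10), 2.0)
        b = self._spot((5, 10, 13), 1.0)  # 3 px
        c = self._spot((5, 12, 12), 1.5)  # sqrt(8) ~ 2.83 px
        kept = merge_candidates([[a], [b], [c]], dedupe_radius_px=2.0)
        assert set(kept) == {a, b, c}

    def test_z_distance_uses_anisotropy(self):
        # 1 z-step at 110/40 nm voxels is 2.75 xy-pixel units -> not a duplicate
        a = self._spot((5, 10, 10), 2.0)
        b = self._spot((6, 10, 10), 1.0)
        kept = merge_candidates([[a], [b]], 2.0, voxel_xy_nm=40, voxel_z_nm=110)
        assert set(kept) == {a, b}
        # with isotropic voxels the same pair is a duplicate
        kept = merge_candidates([[a], [b]], 2.0, voxel_xy_nm=40, voxel_z_nm=40)
        assert kept == [a]

    def test_idempotent_and_no_violating_pair(self):
        rng = np.random.default_rng(0)
        z_scale = 110.0 / 40.0
        for _ in range(100):
            spots = [
                self._spot(idx, peak)
                for idx, peak in zip(
                    rng.integers(0, 20, size=(30, 3)), rng.random(30)
                )
            ]
            kept = merge_candidates([spots], dedupe_radius_px=2.0)
            again = merge_candidates([kept], dedupe_radius_px=2.0)
            assert kept == again
            # all-pairs brute force: no surviving pair within the radius
            arr = np.array([k.voxel_index for k in kept], dtype=float)
            arr *= np.array([z_scale, 1.0, 1.0])
            for i in range(len(arr)):
                for j in range(i + 1, len(arr)):
                    assert np.linalg.norm(arr[i] - arr[j]) > 2.0


def test_union_property_detects_nearly_all_true_vesicles():
    """Every resolvable rendered vesicle yields a merged candidate nearby.

    Vesicles are spaced so neighbouring blobs do not fuse into one
    thresholded component; fused pairs are a resolution limit, not a
    detector failure.
    """
    cfg = v.ImagingConfig(
        shape_voxels=(16, 128, 128),
        noise_gaussian_sd=0.1,
        chromatic_shift_nm=((0.0, 0.0, 0.0), (0.0, 30.0, -20.0), (20.0, -20.0, 10.0)),
        seed=11,
    )
    truth = v.sample_vesicle_field(70, v.category_fractions(triple=1.0), 550.0, 11, cfg)
    cell = v.render_stack(truth, cfg)
    cands = v.detect_all(cell.channels)
    voxel = cell.channels[0].voxel_sizes_nm()
    found = 0
    for t in cell.truth:
        tp = np.asarray(t.position_nm) / voxel
        ok = any(
            np.linalg.norm((np.asarray(c.voxel_index) - tp)) <= 2.0 for c in cands
        )
        found += ok
    assert found / len(cell.truth) >= 0.95
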