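"""Separation prefilter, spherical-mask intensities, calls and summaries."""

import numpy as np
import pytest

import vesicoloc as v
from vesicoloc.classification import (
    ChannelNormalization,
    VesicleRecord,
    classify_vesicle,
    measure_intensity,
    prefilter_by_separation,
    summarize_cell,
)
from vesicoloc.localization import LocalizedSpot
from vesicoloc.stack_io import VoxelGrid


def _spot(positions, vid=0):
    return LocalizedSpot(
        vesicle_id=vid,
        positions_nm=np.asarray(positions, float),
        fit_amplitude=np.ones(3),
        fit_sigma_nm=np.full((3, 2), 80.0),
        fit_converged=np.ones(3, bool),
    )


class TestPrefilter:
    def test_close_triplet_passes(self):
        # pairwise distances 50, 60, ~78 nm, all < 200
        s = _spot([[0, 0, 0], [0, 0, 50], [0, 60, 0]])
        assert prefilter_by_separation([s], 200.0)[0]

    def test_one_distant_channel_fails(self):
        s = _spot([[0, 0, 0], [0, 0, 50], [0, 0, 210]])
        assert not prefilter_by_separation([s], 200.0)[0]

    def test_exactly_at_threshold_fails(self):
        s = _spot([[0, 0, 0], [0, 0, 200.0], [0, 0, 100]])
        assert not prefilter_by_separation([s], 200.0)[0]

    def test_identical_positions_pass(self):
        s = _spot([[500, 500, 500]] * 3)
        assert prefilter_by_separation([s], 200.0)[0]


def _brute_force_intensity(grid, centre_nm, radius_nm):
    """Literal triple loop over all voxels applying the sphere test."""
    voxel = grid.voxel_sizes_nm()
    vals = []
    nz, ny, nx = grid.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                d = np.linalg.norm(np.array([z, y, x]) * voxel - np.asarray(centre_nm))
                if d <= radius_nm:
                    vals.append(grid.data[z, y, x] / grid.data.max())
    return float(np.mean(vals) - (grid.data / grid.data.max()).mean())


class TestMeasureIntensity:
    def test_uniform_image_measures_zero(self):
        g = VoxelGrid(np.full((8, 24, 24), 3.0), 40.0, 110.0, "INSL5")
        norm = ChannelNormalization(g)
        val = measure_intensity(norm, (4 * 110.0, 12 * 40.0, 12 * 40.0), 150.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_single_bright_voxel_gives_one_over_k(self):
        data = np.zeros((8, 24, 24))
        data[4, 12, 12] = 1.0
        g = VoxelGrid(data, 40.0, 110.0, "INSL5")
        centre = np.array([4, 12, 12]) * g.voxel_sizes_nm()
        # enumerate the in-sphere voxels by brute force
        k = 0
        for z in range(8):
            for y in range(24):
                for x in range(24):
                    if np.linalg.norm(np.array([z, y, x]) * g.voxel_sizes_nm() - centre) <= 150.0:
                        k += 1
        norm = ChannelNormalization(g)
        expected = 1.0 / k - norm.background
        assert measure_intensity(norm, centre, 150.0) == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_rendered_spot(self):
        from conftest import render_single_spot

        cell, truth = render_single_spot(position_px=(7.3, 12.4, 11.8))
        g = cell.channels[0]
        norm = ChannelNormalization(g)
        ours = measure_intensity(norm, truth.position_nm, 150.0)
        brute = _brute_force_intensity(g, truth.position_nm, 150.0)
        assert ours == pytest.approx(brute, abs=1e-12)

    def test_empty_sphere_raises(self):
        g = VoxelGrid(np.ones((8, 24, 24)), 500.0, 500.0, "INSL5")
        with pytest.raises(ValueError, match="no voxel centres"):
            measure_intensity(ChannelNormalization(g), (1250.0, 1250.0, 1250.0), 150.0)


class TestClassifyVesicle:
    @pytest.mark.parametrize(
        "intensities,category",
        [
            ((0.06, 0.06, 0.06), "triple"),
            ((0.06, 0.01, 0.01), "single_INSL5"),
            ((0.01, 0.06, 0.01), "single_PYY"),
            ((0.06, 0.06, 0.01), "double_INSL5_PYY"),
            ((0.03, 0.06, 0.06), "indeterminate"),  # dead band
            ((0.05, 0.06, 0.06), "indeterminate"),  # exact threshold
            ((0.01, 0.01, 0.01), "indeterminate"),  # nothing present
        ],
    )
    def test_threshold_logic(self, intensities, category):
        calls, cat = classify_vesicle(intensities, 0.05, 0.02)
        assert cat == category

    def test_monotone_in_intensity(self):
        """Raising one channel's intensity never demotes its call."""
        order = {"negative": 0, "indeterminate": 1, "positive": 2}
        grid = np.linspace(-0.01, 0.10, 23)
        for other in (0.01, 0.03, 0.06):
            ranks = [
                order[classify_vesicle((x, other, other), 0.05, 0.02)[0][0]]
                for x in grid
            ]
            assert all(b >= a for a, b in zip(ranks, ranks[1:]))


class TestCallConsistency:
    """Calls and category agree for arbitrary intensity triples."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.tuples(
            st.floats(-0.1, 0.3, allow_nan=False),
            st.floats(-0.1, 0.3, allow_nan=False),
            st.floats(-0.1, 0.3, allow_nan=False),
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_category_matches_calls(self, intensities):
        calls, category = classify_vesicle(intensities, 0.05, 0.02)
        n_pos = sum(c == "positive" for c in calls)
        n_ind = sum(c == "indeterminate" for c in calls)
        if n_ind > 0 or n_pos == 0:
            assert category == "indeterminate"
        elif n_pos == 3:
            assert category == "triple"
        elif n_pos == 2:
            assert category.startswith("double_")
        else:
            assert category.startswith("single_")
        for value, call in zip(intensities, calls):
            if value > 0.05:
                assert call == "positive"
            elif value < 0.02:
                assert call == "negative"
            else:
                assert call == "indeterminate"


def _record(vid, category, prefilter=True):
    return VesicleRecord(
        vesicle_id=vid,
        positions_nm=np.zeros((3, 3)),
        norm_intensity=(0.1, 0.1, 0.1),
        call=("positive",) * 3,
        prefilter_pass=prefilter,
        category=category,
    )


class TestSummarizeCell:
    def test_nine_triple_one_single(self):
        records = [_record(i, "triple") for i in range(9)]
        records.append(_record(9, "single_PYY"))
        s = summarize_cell(records, "c1")
        assert s.pct_triple == pytest.approx(90.0)
        assert s.pct_single == pytest.approx(10.0)
        assert s.pct_single + s.pct_double + s.pct_triple == pytest.approx(100.0)

    def test_all_excluded(self):
        records = [_record(i, "excluded", prefilter=False) for i in range(5)]
        s = summarize_cell(records, "c2")
        assert s.n_prefilter_pass == 0
        assert np.isnan(s.pct_triple)

    def test_counts_match_independent_tally(self):
        rng = np.random.default_rng(4)
        cats = [
            "triple", "single_INSL5", "single_PYY", "single_GLP1",
            "double_INSL5_PYY", "double_INSL5_GLP1", "double_PYY_GLP1",
            "indeterminate", "excluded",
        ]
        for _ in range(20):
            chosen = rng.choice(cats, size=40)
            records = [
                _record(i, c, prefilter=c != "excluded")
                for i, c in enumerate(chosen)
            ]
            s = summarize_cell(records)
            tally = {c: int((chosen == c).sum()) for c in cats}
            assert s.n_triple == tally["triple"]
            assert s.n_single == sum(tally[c] for c in cats if c.startswith("single"))
            assert s.n_double == sum(tally[c] for c in cats if c.startswith("double"))
            assert s.n_indeterminate == tally["indeterminate"]
            assert s.n_detected == 40
            assert (
                s.n_single + s.n_double + s.n_triple + s.n_indeterminate
                == s.n_prefilter_pass
            )


class TestPipelineProperties:
    def test_partition_invariant(self, noisy_cell_result):
        records = noisy_cell_result.records
        s = noisy_cell_result.summary
        n_excluded = sum(r.category == "excluded" for r in records)
        assert (
            n_excluded + s.n_indeterminate + s.n_single + s.n_double + s.n_triple
            == s.n_detected
        )
        # excluded iff prefilter failed
        for r in records:
            assert (r.category == "excluded") == (not r.prefilter_pass)

    def test_identical_truth_classified_triple(self, noisy_cell_result):
        """Identical ground truth in all channels -> triple calls dominate."""
        s = noisy_cell_result.summary
        n_det = s.n_single + s.n_double + s.n_triple
        assert n_det > 0
        assert s.pct_triple >= 95.0
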