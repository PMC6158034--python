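import numpy as np
import pytest

import vesicoloc as v


@pytest.fixture(scope="session")
def quiet_config():
    """Small noiseless imaging geometry for exact-value tests."""
    return v.ImagingConfig(
        shape_voxels=(14, 64, 64),
        noise_gaussian_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noisy_triple_cell():
    """A moderate noisy cell, all vesicles triple-labelled, shift <= 1 px."""
    cfg = v.ImagingConfig(
        shape_voxels=(16, 128, 128),
        noise_gaussian_sd=0.1,
        chromatic_shift_nm=((0.0, 0.0, 0.0), (0.0, 30.0, -20.0), (20.0, -20.0, 10.0)),
        seed=11,
    )
    truth = v.sample_vesicle_field(80, v.category_fractions(triple=1.0), 400.0, 11, cfg)
    return v.render_stack(truth, cfg)


@pytest.fixture(scope="session")
def noisy_cell_result(noisy_triple_cell):
    """Full pipeline output on the shared noisy cell (computed once)."""
    return v.analyze_cell(noisy_triple_cell.channels, cell_id="shared")


def render_single_spot(
    position_px=(7.0, 32.0, 32.0),
    amplitude=1.0,
    config=None,
    **overrides,
):
    """One triple-labelled vesicle at a (possibly off-grid) pixel position."""
    cfg = config or v.ImagingConfig(
        shape_voxels=(14, 64, 64), noise_gaussian_sd=0.0, **overrides
    )
    pos_nm = tuple(np.asarray(position_px) * cfg.voxel_sizes_nm())
    truth = [
        v.GroundTruthVesicle(pos_nm, (amplitude,) * 3, frozenset(v.CHANNELS))
    ]
    return v.render_stack(truth, cfg), truth[0]
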