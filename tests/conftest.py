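import numpy as np
import pytest

from microtma import DetectionParams, SectionParams, generate_section


@pytest.fixture(scope="session")
def default_section():
    """One mid-density section at scan resolution, shared read-only."""
    params = SectionParams(
        n_cells=400, seed=42, tumor_fraction=0.4,
        marker_frac_tumor=0.6, marker_frac_normal=0.05,
    )
    image, truth = generate_section(params)
    return params, image, truth


@pytest.fixture(scope="session")
def fast_section():
    """A coarse-resolution section for pipeline-level tests."""
    params = SectionParams(
        n_cells=200, seed=7, pixel_size_um=1.0, tumor_fraction=0.5,
        marker_frac_tumor=0.3, marker_frac_normal=0.05,
    )
    image, truth = generate_section(params)
    return params, image, truth


@pytest.fixture
def detection_params():
    return DetectionParams()


def match_to_truth(centers: np.ndarray, truth, radius_px: float):
    """Greedy 1-1 matching of detections to true centres within a radius."""
    from scipy.spatial import cKDTree

    gt = truth.cells[["x", "y"]].to_numpy()
    if len(centers) == 0 or len(gt) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    tree = cKDTree(gt)
    dist, idx = tree.query(centers, k=1)
    det_i = np.flatnonzero(dist <= radius_px)
    return det_i, idx[det_i]
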