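import numpy as np
import pytest

from spheromet import SpheroidScene, generate_spheroid_image
from spheromet.segmentation import segment_image


@pytest.fixture(scope="session")
def scenes20():
    """Twenty seeded noiseless default scenes with their segmentations.

    Default scene: 256x256 px at 2 µm/px, 120 µm spheroid, 30 matrix cells
    (1/3 dead), 3 conglomerates. Returns list of (scene, image, truth, mask).
    """
    out = []
    for seed in range(20):
        scene = SpheroidScene(seed=seed)
        img, gt = generate_spheroid_image(scene)
        mask = segment_image(img)
        assert mask is not None
        out.append((scene, img, gt, mask))
    return out


@pytest.fixture(scope="session")
def symmetric_disk():
    """Noiseless rotationally symmetric spheroid, no satellite objects."""
    scene = SpheroidScene(seed=101, n_matrix_cells=0, n_conglomerates=0,
                          spheroid_radius=200.0)
    img, gt = generate_spheroid_image(scene)
    mask = segment_image(img)
    return scene, img, gt, mask


def brute_force_min_dist(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Independent oracle: per point, min Euclidean distance to target set."""
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = np.min(np.hypot(targets[:, 0] - p[0], targets[:, 1] - p[1]))
    return out
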