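import numpy as np
import pytest

from dtbc.image_io import AnalysisMask, CalibratedImage
from dtbc.synthetic_data import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def cohort_2000():
    """Shared mid-size synthetic cohort with default clinical structure."""
    return simulate_cohort(CohortSpec(n_patients=2000, seed=42))


@pytest.fixture()
def white_image():
    """64x64 all-white calibrated image at 1 um/px with a full mask."""
    pixels = np.full((64, 64, 3), 255, dtype=np.uint8)
    image = CalibratedImage(pixels=pixels, microns_per_pixel=1.0)
    mask = AnalysisMask(mask=np.ones((64, 64), dtype=bool), microns_per_pixel=1.0)
    return image, mask


def flood_fill_areas(mask: np.ndarray, microns_per_pixel: float) -> list[float]:
    """Independent 8-connected component areas via explicit stack flood fill.

    Deliberately naive (pure-Python BFS) so it shares no code with the
    labeling implementation under test.
    """
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    h, w = mask.shape
    areas = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not visited[i, j]:
                stack = [(i, j)]
                visited[i, j] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < h
                                and 0 <= nx < w
                                and mask[ny, nx]
                                and not visited[ny, nx]
                            ):
                                visited[ny, nx] = True
                                stack.append((ny, nx))
                areas.append(size * microns_per_pixel**2)
    return areas


def recount_buds(
    mask: np.ndarray,
    microns_per_pixel: float,
    artifact_min: float = 150.0,
    bud_max: float = 950.0,
) -> tuple[int, int]:
    """Brute-force (dtbc, n_regions) recount from a boolean stain mask."""
    areas = flood_fill_areas(mask, microns_per_pixel)
    kept = [a for a in areas if a >= artifact_min]
    return sum(1 for a in kept if a < bud_max), len(kept)
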