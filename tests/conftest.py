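import numpy as np
import pytest
from scipy import ndimage

from myoslip.coupling import records_to_frame
from myoslip.pipeline import run_slippage
from myoslip.segmentation import annotations_from_mask
from myoslip.synthetic import SyntheticMovieSpec, generate_movie


@pytest.fixture(scope="session")
def small_spec():
    """Compact early-stage movie: 12.8 µm field, ~2.3 min, 5 membrane frames."""
    return SyntheticMovieSpec(
        image_shape=(128, 128), center=(64.0, 64.0), initial_radius=5.0,
        n_myosin_frames=25, seed=11)


@pytest.fixture(scope="session")
def small_movie(small_spec):
    return generate_movie(small_spec)


@pytest.fixture(scope="session")
def small_annotations(small_movie):
    movie, truth = small_movie
    rng = np.random.default_rng(42)
    ann = []
    n_mem = len(movie.membrane_frames)
    for fi in (0, n_mem // 2, n_mem - 1):
        ann.extend(annotations_from_mask(truth.mask(fi), fi, rng, n_per_class=250))
    return ann


@pytest.fixture(scope="session")
def small_pipeline(small_movie, small_annotations):
    """Full pipeline run on the small movie (shared; treat as read-only)."""
    movie, truth = small_movie
    result = run_slippage(movie, annotations=small_annotations, seed=7)
    return result, records_to_frame(result.records)


@pytest.fixture(scope="session")
def textured_frame():
    """Smooth random texture with full coverage, for flow oracles."""
    rng = np.random.default_rng(0)
    img = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (200, 200)), 3.0)
    img -= img.min()
    return img / img.max() * 1000.0
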