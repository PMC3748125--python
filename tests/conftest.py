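import numpy as np
import pytest

import aggloseg as ag


@pytest.fixture
def two_strip():
    """Two horizontal strips, one edge, constant cue."""
    labels = np.array([[1, 1], [2, 2]])
    cue = np.full((2, 2), 0.5)
    return ag.build_rag(labels, [cue])


@pytest.fixture
def quad():
    """2x2 block of four superpixels (square adjacency graph)."""
    labels = np.array([[1, 2], [3, 4]])
    cue = np.linspace(0, 0.9, 4).reshape(2, 2)
    return ag.build_rag(labels, [cue])


def random_label_volume(rng, shape, n_labels):
    """Random connected-ish labelling: nearest of n seed pixels."""
    from scipy.spatial import cKDTree

    n_pixels = int(np.prod(shape))
    seeds = rng.choice(n_pixels, size=n_labels, replace=False)
    pts = np.stack(np.unravel_index(seeds, shape), axis=1)
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, len(shape))
    _, nearest = cKDTree(pts).query(grid)
    return (nearest + 1).reshape(shape).astype(np.int32)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def clean_spec(seed=0):
    """A learnable 64x64 phantom: visible boundaries, mild texture noise."""
    return ag.PhantomSpec(
        shape=(64, 64),
        n_segments=6,
        superpixel_spacing=5,
        noise_sd=0.05,
        boundary_strength=(0.7, 1.1),
        texture_noise_sd=0.1,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 learnable phantom shared by slower integration tests."""
    return ag.make_phantom(clean_spec(0))
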