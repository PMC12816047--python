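import numpy as np
import pandas as pd
import pytest

from spatialtime import RegionMask, SpotTable, build_scene


@pytest.fixture(scope="session")
def default_scene():
    """The default simulated scene (2025 spots, disk anlagen), seed 1."""
    return build_scene(seed=1)


@pytest.fixture
def tiny_table():
    """Three spots, two genes, with scores."""
    spots = pd.DataFrame(
        {"spot_id": ["a", "b", "c"], "x": [0.0, 3.0, 10.0], "y": [0.0, 4.0, 0.0]}
    )
    counts = np.array([[5, 0, 2], [1, 3, 0]])
    scores = pd.DataFrame({"macrophage": [0.9, 0.6, 0.1], "mpc": [0.1, 0.7, 0.8]})
    return SpotTable(spots=spots, counts=counts, genes=["g1", "g2"], scores=scores)


def random_spot_table(rng: np.random.Generator, n_spots=8, n_genes=4, scores=True):
    spots = pd.DataFrame(
        {
            "spot_id": [f"s{k}" for k in range(n_spots)],
            "x": rng.uniform(0, 50, n_spots).round(3),
            "y": rng.uniform(0, 50, n_spots).round(3),
        }
    )
    counts = rng.poisson(3, size=(n_genes, n_spots))
    sc = None
    if scores:
        sc = pd.DataFrame(
            {
                "ct_a": rng.uniform(0, 1, n_spots).round(6),
                "ct_b": rng.uniform(0, 1, n_spots).round(6),
            }
        )
    return SpotTable(
        spots=spots, counts=counts, genes=[f"g{k}" for k in range(n_genes)],
        scores=sc,
    )


def random_mask(rng: np.random.Generator, shape=(16, 16), p=0.2) -> RegionMask:
    raster = rng.random(shape) < p
    if not raster.any():
        raster[shape[0] // 2, shape[1] // 2] = True
    return RegionMask(raster=raster)
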