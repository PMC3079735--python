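import numpy as np
import pytest

from ecmremodel import (
    ImageStack,
    SimulationParams,
    detect_layers,
    max_projection,
    rescale_to_225,
    score_stack,
    segment_cell_region,
    simulate_matrix_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A tiny 3-channel stack with random integer intensities."""
    shape = (4, 32, 32)
    channels = {
        name: rng.integers(0, 226, size=shape).astype(float)
        for name in ("nuclei", "fibronectin", "tmp")
    }
    return ImageStack(channels=channels)


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter synthetic field (no remodeling), reused."""
    return simulate_matrix_stack(SimulationParams(seed=11))


def score_simulated_field(seed: int, phenotype: str = "none", **overrides):
    """Full path: simulate -> scale -> layer -> segment -> score."""
    params = SimulationParams(seed=seed, phenotype=phenotype, **overrides)
    stack, truth = simulate_matrix_stack(params)
    scaled = rescale_to_225(stack, "fixed-range", lo=0.0, hi=225.0)
    partition = detect_layers(scaled)
    region = segment_cell_region(
        max_projection(scaled, "nuclei"), pixel_size_um=params.pixel_size_um
    )
    scores = score_stack(scaled, partition, region)
    return scores, partition, region, truth


def layer_means(scores):
    out = {}
    for layer in ("top", "middle", "bottom"):
        out[layer] = float(
            np.mean([s.score_percent for s in scores if s.layer == layer])
        )
    return out
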