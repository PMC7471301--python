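import numpy as np
import pytest

from orbimetry import (
    GraphCutParams,
    PhantomSpec,
    SeedSet,
    generate_phantom,
    keep_seeded_component,
    segment_eyeball,
)
from orbimetry.phantom import suggest_seeds


@pytest.fixture(scope="session")
def default_phantom():
    """Two-eye default phantom with moderate noise, shared across tests."""
    spec = PhantomSpec(noise_sigma=10.0, seed=123)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def segmented_right_eye(default_phantom):
    """Segmented right eyeball of the default phantom (graph cut + component)."""
    spec, volume, _ = default_phantom
    seeds = suggest_seeds(spec, "right")
    mask = keep_seeded_component(segment_eyeball(volume, seeds), seeds)
    return spec, volume, seeds, mask


def random_micro_instance(rng, shape=(4, 4, 1)):
    """A tiny random two-intensity volume with one fg and one bg seed."""
    from orbimetry import CTVolume

    base = rng.choice([20.0, -80.0], size=shape)
    data = base + rng.normal(0.0, 60.0, size=shape)
    vol = CTVolume(data=data)
    n = int(np.prod(shape))
    pick = rng.choice(n, size=2, replace=False)
    idx = np.array(np.unravel_index(pick, shape)).T
    seeds = SeedSet(foreground=idx[:1], background=idx[1:])
    params = GraphCutParams(
        lam=float(rng.uniform(0.2, 3.0)), sigma_edge=float(rng.uniform(20.0, 80.0))
    )
    return vol, seeds, params
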