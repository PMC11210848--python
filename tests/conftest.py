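import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nbacklight import VoxelGrid, generate_design
from nbacklight.bold_extraction import TrialPatternSet

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def session_design():
    """The study's session layout: 3 blocks each of 0-, 1-, 2-back, 16 stimuli, 4 targets."""
    return generate_design(seed=1)


@pytest.fixture(scope="session")
def mini_design():
    """A short two-level design: one block of 12 stimuli per level -> 10 valid 2-back trials."""
    return generate_design(levels=(0, 2), blocks_per_level=1, stimuli_per_block=12, targets_per_block=3, seed=2)


def make_pattern_sets(
    n_participants=4,
    n_per_class=6,
    shape=(5, 5, 4),
    offset=0.0,
    noise=1.0,
    seed=0,
    group="control",
):
    """Hand-built trial pattern sets: Gaussian rows, follow-up rows shifted
    by a constant per-voxel offset field shared across participants."""
    rng = np.random.default_rng(seed)
    grid = VoxelGrid(shape)
    mask = np.ones(shape, dtype=bool)
    nvox = int(mask.sum())
    shift = offset * rng.standard_normal(nvox)
    sets = []
    for p in range(n_participants):
        data = noise * rng.standard_normal((2 * n_per_class, nvox))
        data[n_per_class:] += shift[None, :]
        labels = pd.DataFrame(
            {
                "time_point": ["baseline"] * n_per_class + ["followup"] * n_per_class,
                "level": 2,
                "block": 0,
                "trial": list(range(n_per_class)) * 2,
            }
        )
        sets.append(
            TrialPatternSet(
                participant=f"p{p:02d}",
                group=group,
                data=data,
                labels=labels,
                mask=mask,
                grid=grid,
                lag_window=(2, 3),
            )
        )
    return sets


@pytest.fixture
def pattern_sets_factory():
    return make_pattern_sets
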