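import numpy as np
import pytest

from embed import EMBED, CountTensor
from embed.glv import (
    counts_to_tensor,
    random_stable_glv_system,
    sample_read_counts,
    simulate_glv,
)


def make_tensor(seed=0, n_otus=6, n_subjects=2, n_times=12, missing=False,
                max_count=40):
    """Random dense (or gapped) count tensor for unit tests."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, max_count, size=(n_otus, n_subjects, n_times))
    mask = np.ones((n_subjects, n_times), dtype=bool)
    if missing:
        # knock out interior samples, keep first/last so spans are intact
        holes = rng.choice(np.arange(1, n_times - 1),
                           size=max(1, n_times // 4), replace=False)
        mask[rng.integers(n_subjects, size=len(holes)), holes] = False
    counts = counts * mask[None, :, :]
    return CountTensor(
        counts=counts.astype(float),
        subject_ids=[f"s{i}" for i in range(n_subjects)],
        time_stamps=np.arange(n_times),
        otu_ids=[f"otu{i}" for i in range(n_otus)],
        observed_mask=mask,
    )


@pytest.fixture(scope="session")
def small_tensor():
    return make_tensor(seed=0)


@pytest.fixture(scope="session")
def gapped_tensor():
    return make_tensor(seed=1, n_times=16, missing=True)


@pytest.fixture(scope="session")
def fitted(small_tensor):
    return EMBED(small_tensor, 3).fit(seed=0)


@pytest.fixture(scope="session")
def fitted_gapped(gapped_tensor):
    return EMBED(gapped_tensor, 2).fit(seed=0)


@pytest.fixture(scope="session")
def glv_tensor():
    """Single-subject community sampled from a stable gLV ground truth."""
    system = random_stable_glv_system(n_species=12, seed=2, t_days=40)
    days, _, prop = simulate_glv(system, t_days=40)
    counts = sample_read_counts(prop, depth=10_000, seed=2)[0]
    return counts_to_tensor(counts, days)


@pytest.fixture(scope="session")
def glv_fitted(glv_tensor):
    return EMBED(glv_tensor, 3).fit(seed=2)
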