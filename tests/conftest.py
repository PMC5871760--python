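import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aidlicense.bioid import SpectralCountMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(counts: dict[str, list[int]], baits: list[str],
                birA: str = "BIRA") -> SpectralCountMatrix:
    """Build a small spectral-count matrix from a prey -> counts dict.

    ``baits`` gives the bait label of each sample column; replicate numbers
    are assigned per bait in order.
    """
    reps: dict[str, int] = {}
    sample_ids = []
    for b in baits:
        reps[b] = reps.get(b, 0) + 1
        sample_ids.append(f"{b}.{reps[b]}")
    df = pd.DataFrame.from_dict(counts, orient="index", columns=sample_ids)
    samples = pd.DataFrame(
        {"bait": baits, "replicate": [int(s.split(".")[1]) for s in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SpectralCountMatrix(counts=df, samples=samples, birA_prey_id=birA)


@pytest.fixture
def small_matrix() -> SpectralCountMatrix:
    """12 preys + BirA* row, 2 replicates for each of the four baits."""
    rng = np.random.default_rng(42)
    baits = ["WT", "WT", "MUT1", "MUT1", "MUT2", "MUT2", "A2", "A2"]
    counts = {"BIRA": [100] * 8}
    for i in range(12):
        counts[f"P{i:02d}"] = list(rng.poisson(30, size=8))
    return make_matrix(counts, baits)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
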