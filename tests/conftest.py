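import numpy as np
import pytest

from kldm import CountMatrix, EFMatrix, SimConfig, gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Single-condition dataset small enough for fast fits."""
    cfg = SimConfig(K=1, P=10, Q=2, n_range=(120, 120), seed=42)
    return gen_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Single-condition dataset sized for edge-recovery checks."""
    cfg = SimConfig(K=1, P=20, Q=3, n_range=(400, 400), seed=0)
    return gen_dataset(cfg)


@pytest.fixture()
def tiny_counts():
    counts = np.array([[5, 3, 2], [1, 8, 1], [4, 4, 2], [2, 2, 6]])
    return CountMatrix(counts, ["s1", "s2", "s3", "s4"], ["o1", "o2", "o3"])


@pytest.fixture()
def tiny_efs():
    vals = np.array([[0.1, 1.0], [0.2, 0.8], [-0.3, 1.2], [0.05, 0.9]])
    return EFMatrix(vals, ["s1", "s2", "s3", "s4"], ["e1", "e2"])
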