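import numpy as np
import pytest

from regjoint.hapcore import HaplotypeSystem

H4 = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)

# the two-SNP frequency sets used throughout the simulation study:
# panel A gives pairwise r2 = 0 exactly, panel B r2 ~= 0.195
PI_A = np.array([0.10, 0.30, 0.15, 0.45])
PI_B = np.array([0.42, 0.18, 0.10, 0.30])


@pytest.fixture
def sys_r2_zero() -> HaplotypeSystem:
    return HaplotypeSystem(H4.copy(), PI_A.copy())


@pytest.fixture
def sys_r2_02() -> HaplotypeSystem:
    return HaplotypeSystem(H4.copy(), PI_B.copy())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250921)


def random_system(rng: np.random.Generator, m: int = 2, with_beta: bool = False,
                  min_freq: float = 0.02) -> HaplotypeSystem:
    """A random full-support haplotype system over m SNPs."""
    k = 2**m
    H = np.array(
        [[(i >> (m - 1 - j)) & 1 for j in range(m)] for i in range(k)], dtype=np.int8
    )
    pi = rng.dirichlet(np.ones(k)) * (1 - k * min_freq) + min_freq
    beta = rng.standard_normal(k) if with_beta else None
    return HaplotypeSystem(H, pi, beta)
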