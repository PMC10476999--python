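import numpy as np
import pytest

from ctdenoise import CTImage, Domain, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_hu_image(rng):
    return CTImage(rng.uniform(-1000, 1000, size=(16, 16)), Domain.HU)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(PhantomSpec(size=64, seed=42))


def naive_dft2(f: np.ndarray) -> np.ndarray:
    """Brute-force O(m^2 n^2) double-sum DFT (test oracle)."""
    m, n = f.shape
    F = np.zeros((m, n), dtype=complex)
    for u in range(m):
        for v in range(n):
            for x in range(m):
                for y in range(n):
                    F[u, v] += f[x, y] * np.exp(-2j * np.pi * (u * x / m + v * y / n))
    return F


def naive_idft2(F: np.ndarray) -> np.ndarray:
    """Brute-force inverse DFT with the 1/(mn) factor (test oracle)."""
    m, n = F.shape
    f = np.zeros((m, n), dtype=complex)
    for x in range(m):
        for y in range(n):
            for u in range(m):
                for v in range(n):
                    f[x, y] += F[u, v] * np.exp(2j * np.pi * (u * x / m + v * y / n))
    return f / (m * n)


def naive_hf_loss(g: np.ndarray, t: np.ndarray, mask: np.ndarray) -> float:
    """Independent HFLoss oracle: naive DFT -> mask -> naive inverse -> mean abs."""
    hp_g = np.real(naive_idft2(mask * naive_dft2(g)))
    hp_t = np.real(naive_idft2(mask * naive_dft2(t)))
    return float(np.mean(np.abs(hp_g - hp_t)))
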