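import numpy as np
import pytest

from lonenet.params import GroundTruthGGM, IsingParameters


def random_ising(rng: np.random.Generator, p: int, positive: bool = False) -> IsingParameters:
    """A random small Ising parameter set for oracle comparisons."""
    lo = 0.0 if positive else -0.8
    omega = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            omega[i, j] = omega[j, i] = rng.uniform(lo, 0.9)
    tau = rng.uniform(-1.5, 0.5, size=p)
    return IsingParameters([f"S{i + 1}" for i in range(p)], tau, omega)


def chain_ising(p: int = 10, weight: float = 1.2, tau: float = -1.0) -> IsingParameters:
    omega = np.zeros((p, p))
    for i in range(p - 1):
        omega[i, i + 1] = omega[i + 1, i] = weight
    return IsingParameters([f"S{i + 1}" for i in range(p)], np.full(p, tau), omega)


def chain_ggm(p: int = 14, off: float = -0.3) -> GroundTruthGGM:
    K = np.eye(p)
    for i in range(p - 1):
        K[i, i + 1] = K[i + 1, i] = off
    return GroundTruthGGM([f"F{i + 1}" for i in range(p)], K)


def set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label tuples."""

    def rec(i, maxk, cur):
        if i == n:
            yield tuple(cur)
            return
        for k in range(maxk + 1):
            cur.append(k)
            yield from rec(i + 1, max(maxk, k + 1), cur)
            cur.pop()

    yield from rec(0, 0, [])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
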