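"""Seeded generators of synthetic three-variable data.

Emulates the genetics use case: two discrete source variables (loci) drive
a target through a discrete function, with two corruptions of the ideal
picture — output noise (a fraction of targets replaced by uniform symbols)
and input coupling (a mixture with a diagonal-concentrated source
distribution, standing in for linkage disequilibrium between loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distribution import CountTable, JointDistribution
from .functions import DiscreteFunction

__all__ = ["GeneratorConfig", "generate_observations", "random_distribution",
           "coupled_input_distribution"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling plan for observations of (X, Y, Z = f(X, Y) + noise).

    Parameters
    ----------
    function
        The generating discrete function.
    n
        Number of observations.
    noise
        Probability, in [0, 1], that an output symbol is replaced by a
        uniform random symbol.
    coupling
        Mixture weight, in [0, 1], of the uniform-on-diagonal source
        distribution: p(x, y) = (1 - coupling)/N^2 + coupling * [x == y]/N.
    seed
        Seed for all randomness.
    """

    function: DiscreteFunction
    n: int
    noise: float = 0.0
    coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")


def coupled_input_distribution(n: int, coupling: float) -> np.ndarray:
    """Source distribution mixing uniform i.i.d. with a uniform diagonal."""
    inp = np.full((n, n), (1.0 - coupling) / (n * n))
    inp[np.diag_indices(n)] += coupling / n
    return inp


def generate_observations(cfg: GeneratorConfig) -> CountTable:
    """Draw seeded observations and aggregate them into a count table."""
    n_sym = cfg.function.alphabet_size
    rng = np.random.default_rng(cfg.seed)
    inp = coupled_input_distribution(n_sym, cfg.coupling).ravel()
    cells = rng.choice(n_sym * n_sym, size=cfg.n, p=inp)
    xs, ys = cells // n_sym, cells % n_sym
    zs = cfg.function.table[xs, ys].copy()
    if cfg.noise > 0.0:
        corrupt = rng.random(cfg.n) < cfg.noise
        zs[corrupt] = rng.integers(0, n_sym, size=int(corrupt.sum()))
    counts = np.zeros((n_sym, n_sym, n_sym), dtype=np.int64)
    np.add.at(counts, (xs, ys, zs), 1)
    xs_u, ys_u, zs_u = np.nonzero(counts)
    return CountTable(
        tuple(
            (int(x), int(y), int(z), int(counts[x, y, z]))
            for x, y, z in zip(xs_u, ys_u, zs_u)
        )
    )


def random_distribution(
    alphabet_sizes: tuple[int, int, int], concentration: float = 1.0, seed: int = 0
) -> JointDistribution:
    """Symmetric-Dirichlet random tensor over all cells (a test fixture)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    n_cells = int(np.prod(alphabet_sizes))
    probs = rng.dirichlet(np.full(n_cells, concentration))
    return JointDistribution(probs.reshape(alphabet_sizes))
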