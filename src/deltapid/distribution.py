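"""Discrete three-variable joint distributions and classical Shannon measures.

The universal data object of the package is :class:`JointDistribution`, a
dense non-negative probability tensor ``p[x, y, z]`` over three finite
alphabets.  Empirical data enter as a :class:`CountTable` and are normalized.
All information measures are in bits (base-2 logarithms), with the usual
convention ``0 * log 0 = 0``.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from ._validate import axes_of

__all__ = [
    "JointDistribution",
    "CountTable",
    "ShannonProfile",
    "normalize_counts",
    "entropy",
    "mutual_information",
    "shannon_profile",
]

#: probabilities below this are treated as exact zeros in entropy sums
_ZERO_TOL = 1e-15
_NORM_TOL = 1e-12


@dataclass(frozen=True)
class JointDistribution:
    """Dense joint probability tensor of three discrete variables.

    Parameters
    ----------
    values
        Array of shape ``(Nx, Ny, Nz)`` with non-negative entries summing
        to one.  Symbols are 0-based consecutive integers.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-way tensor, got ndim={arr.ndim}")
        if np.any(arr < -_ZERO_TOL):
            raise ValueError("probabilities must be non-negative")
        total = arr.sum()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"probabilities must sum to 1, got {total!r}")
        arr = np.where(arr < _ZERO_TOL, 0.0, arr)
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def alphabet_sizes(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def marginal(self, subset: str | Iterable[str]) -> np.ndarray:
        """Marginal probability array over ``subset`` (axes in X, Y, Z order)."""
        keep = axes_of(subset)
        drop = tuple(ax for ax in range(3) if ax not in keep)
        return self.values.sum(axis=drop) if drop else self.values

    @classmethod
    def from_array(cls, values: np.ndarray, *, normalize: bool = False) -> "JointDistribution":
        arr = np.asarray(values, dtype=float)
        if normalize:
            total = arr.sum()
            if total <= 0:
                raise ValueError("cannot normalize an all-zero tensor")
            arr = arr / total
        return cls(arr)


@dataclass(frozen=True)
class CountTable:
    """Sparse record of observed (x, y, z) co-occurrence counts."""

    records: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        recs = []
        for rec in self.records:
            x, y, z, c = (int(v) for v in rec)
            if c < 0:
                raise ValueError(f"negative count in record {rec!r}")
            if min(x, y, z) < 0:
                raise ValueError(f"negative symbol in record {rec!r}")
            recs.append((x, y, z, c))
        object.__setattr__(self, "records", tuple(recs))

    @property
    def total(self) -> int:
        return sum(c for *_, c in self.records)

    @classmethod
    def from_mapping(cls, counts: dict[tuple[int, int, int], int]) -> "CountTable":
        return cls(tuple((x, y, z, c) for (x, y, z), c in counts.items()))


@dataclass(frozen=True)
class ShannonProfile:
    """Every classical Shannon measure of a three-variable distribution (bits)."""

    h_x: float
    h_y: float
    h_z: float
    h_xy: float
    h_xz: float
    h_yz: float
    h_xyz: float
    i_zx: float = field(init=False)
    i_zy: float = field(init=False)
    i_xy: float = field(init=False)
    i_z_xy: float = field(init=False)
    i_y_xz: float = field(init=False)
    i_x_yz: float = field(init=False)
    co_information: float = field(init=False)
    interaction_information: float = field(init=False)
    omega: float = field(init=False)

    def __post_init__(self) -> None:
        set_ = object.__setattr__
        # pairwise and joint mutual informations from entropy combinations
        set_(self, "i_zx", self.h_x + self.h_z - self.h_xz)
        set_(self, "i_zy", self.h_y + self.h_z - self.h_yz)
        set_(self, "i_xy", self.h_x + self.h_y - self.h_xy)
        set_(self, "i_z_xy", self.h_xy + self.h_z - self.h_xyz)
        set_(self, "i_y_xz", self.h_xz + self.h_y - self.h_xyz)
        set_(self, "i_x_yz", self.h_yz + self.h_x - self.h_xyz)
        ci = (
            self.h_x + self.h_y + self.h_z
            - self.h_xy - self.h_xz - self.h_yz
            + self.h_xyz
        )
        set_(self, "co_information", ci)
        # for an odd number of variables II = -CI
        set_(self, "interaction_information", -ci)
        set_(self, "omega", self.h_x + self.h_y + self.h_z - self.h_xyz)


def normalize_counts(
    counts: CountTable, alphabet_sizes: tuple[int, int, int]
) -> JointDistribution:
    """Turn a count table into a joint distribution over the given alphabets.

    Duplicate cells are summed; unobserved cells are zero.
    """
    nx, ny, nz = alphabet_sizes
    tensor = np.zeros((nx, ny, nz))
    for x, y, z, c in counts.records:
        if x >= nx or y >= ny or z >= nz:
            raise ValueError(
                f"symbol ({x},{y},{z}) outside alphabet {alphabet_sizes}"
            )
        tensor[x, y, z] += c
    total = tensor.sum()
    if total <= 0:
        raise ValueError("count table is all zeros; cannot normalize")
    return JointDistribution(tensor / total)


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > _ZERO_TOL]
    return float(-xlogy(p, p).sum() / np.log(2.0))


def entropy(dist: JointDistribution, subset: str | Iterable[str]) -> float:
    """Joint entropy, in bits, of a non-empty subset of {X, Y, Z}."""
    if not list(subset):
        raise ValueError("entropy requires a non-empty variable subset")
    return _entropy_bits(dist.marginal(subset))


def mutual_information(
    dist: JointDistribution,
    side_a: str | Iterable[str],
    side_b: str | Iterable[str],
    given: str | Iterable[str] = (),
) -> float:
    """(Conditional) mutual information I(A : B | C) in bits.

    Computed from the entropy combination
    ``H(A,C) + H(B,C) - H(A,B,C) - H(C)``.
    """
    a, b, c = axes_of(side_a), axes_of(side_b), axes_of(given)
    if not a or not b:
        raise ValueError("both sides of a mutual information must be non-empty")
    if set(a) & set(b) or set(a) & set(c) or set(b) & set(c):
        raise ValueError("side_a, side_b and given must be pairwise disjoint")
    names = "XYZ"
    sub = lambda axes: "".join(names[i] for i in sorted(axes))  # noqa: E731
    h_ac = entropy(dist, sub(a + c))
    h_bc = entropy(dist, sub(b + c))
    h_abc = entropy(dist, sub(a + b + c))
    h_c = entropy(dist, sub(c)) if c else 0.0
    return h_ac + h_bc - h_abc - h_c


def shannon_profile(dist: JointDistribution) -> ShannonProfile:
    """All subset entropies and derived measures of a distribution."""
    return ShannonProfile(
        h_x=entropy(dist, "X"),
        h_y=entropy(dist, "Y"),
        h_z=entropy(dist, "Z"),
        h_xy=entropy(dist, "XY"),
        h_xz=entropy(dist, "XZ"),
        h_yz=entropy(dist, "YZ"),
        h_xyz=entropy(dist, "XYZ"),
    )
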