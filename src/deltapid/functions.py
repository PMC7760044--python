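"""Enumeration of discrete functions Z = f(X, Y) and the delta-plane atlas.

For an alphabet of size N there are ``N**(N*N)`` total functions of two
arguments.  With uniform independent inputs each non-constant function
induces a joint distribution whose delta coordinates lie on the function
plane; functions sharing one delta point form a *family*.  For N = 3 the
19,683 functions collapse onto 105 families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delta import DeltaCoordinates, UndefinedDeltaError, deltas
from .distribution import JointDistribution

__all__ = [
    "DiscreteFunction",
    "FunctionAtlas",
    "enumerate_functions",
    "function_to_distribution",
    "build_atlas",
]

#: decimal places used to group delta points into families
GROUPING_DECIMALS = 9


@dataclass(frozen=True)
class DiscreteFunction:
    """A total function f: [0,N) x [0,N) -> [0,N), stored as an N x N table."""

    table: np.ndarray  # table[x, y] = f(x, y)

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=np.int64)
        if tab.ndim != 2 or tab.shape[0] != tab.shape[1]:
            raise ValueError("function table must be square")
        n = tab.shape[0]
        if tab.min() < 0 or tab.max() >= n:
            raise ValueError(f"table entries must lie in [0, {n})")
        tab.flags.writeable = False
        object.__setattr__(self, "table", tab)

    @property
    def alphabet_size(self) -> int:
        return self.table.shape[0]

    def __call__(self, x: int, y: int) -> int:
        return int(self.table[x, y])

    @property
    def digits(self) -> tuple[int, ...]:
        """Flattened table in row-major order (the enumeration key)."""
        return tuple(int(v) for v in self.table.ravel())

    def index(self) -> int:
        """Position of this function in base-N counting order."""
        n = self.alphabet_size
        idx = 0
        for d in self.digits:
            idx = idx * n + d
        return idx

    def swap_inputs(self) -> "DiscreteFunction":
        return DiscreteFunction(self.table.T)

    @classmethod
    def from_index(cls, index: int, n: int) -> "DiscreteFunction":
        digits = []
        for _ in range(n * n):
            digits.append(index % n)
            index //= n
        tab = np.array(digits[::-1], dtype=np.int64).reshape(n, n)
        return cls(tab)

    @classmethod
    def xor(cls, n: int) -> "DiscreteFunction":
        """Modular addition (x + y) mod n — the fully synergistic archetype."""
        grid = np.add.outer(np.arange(n), np.arange(n)) % n
        return cls(grid)

    @classmethod
    def projection_x(cls, n: int) -> "DiscreteFunction":
        """Z = X, the fully pairwise archetype."""
        return cls(np.tile(np.arange(n)[:, None], (1, n)))

    @classmethod
    def binary_and(cls) -> "DiscreteFunction":
        return cls(np.array([[0, 0], [0, 1]]))


@dataclass(frozen=True)
class FunctionAtlas:
    """All functions of an alphabet mapped onto delta space, grouped by family.

    Attributes
    ----------
    entries
        DataFrame with one row per function: ``function_id`` (base-N index),
        ``digits`` (table as a string), ``delta_x/y/z``, ``omega``,
        ``family`` (family id, -1 for the degenerate Omega=0 bucket).
    families
        DataFrame with one row per non-degenerate family: rounded delta
        point, member count and the id of the canonical (lexicographically
        smallest) representative function.
    """

    alphabet_size: int
    entries: pd.DataFrame
    families: pd.DataFrame
    degenerate_ids: tuple[int, ...]

    @property
    def n_functions(self) -> int:
        return len(self.entries)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def representative(self, family_id: int) -> DiscreteFunction:
        row = self.families.loc[family_id]
        return DiscreteFunction.from_index(
            int(row["representative_id"]), self.alphabet_size
        )

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def enumerate_functions(n: int, *, allow_large: bool = False):
    """Yield every f: [0,N)^2 -> [0,N) in base-N counting order of its table.

    ``N > 3`` is refused unless ``allow_large`` is set (N = 4 already means
    4**16 ~ 4.3e9 functions).
    """
    if n < 2:
        raise ValueError("alphabet size must be at least 2")
    if n > 3 and not allow_large:
        raise ValueError(
            f"exhaustive enumeration of {n**(n*n)} functions for N={n} "
            "requires allow_large=True"
        )
    for idx in range(n ** (n * n)):
        yield DiscreteFunction.from_index(idx, n)


def function_to_distribution(
    f: DiscreteFunction, input_dist: np.ndarray | None = None
) -> JointDistribution:
    """Joint distribution p(x,y,z) = p(x,y) * [z == f(x,y)].

    ``input_dist`` is the N x N source distribution p(x, y); by default the
    sources are uniform i.i.d.
    """
    n = f.alphabet_size
    if input_dist is None:
        input_dist = np.full((n, n), 1.0 / (n * n))
    inp = np.asarray(input_dist, dtype=float)
    if inp.shape != (n, n):
        raise ValueError(f"input distribution must be {n}x{n}")
    if np.any(inp < 0) or abs(inp.sum() - 1.0) > 1e-12:
        raise ValueError("input matrix is not a probability distribution")
    tensor = np.zeros((n, n, n))
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    tensor[xs, ys, f.table] = inp
    return JointDistribution(tensor)


def _delta_row(f: DiscreteFunction, input_dist) -> tuple[float, float, float, float]:
    dist = function_to_distribution(f, input_dist)
    try:
        d = deltas(dist)
    except UndefinedDeltaError:
        return (np.nan, np.nan, np.nan, 0.0)
    return (d.delta_x, d.delta_y, d.delta_z, d.omega)


def build_atlas(
    n: int,
    input_dist: np.ndarray | None = None,
    grouping_decimals: int = GROUPING_DECIMALS,
    *,
    allow_large: bool = False,
) -> FunctionAtlas:
    """Map every N-letter function onto delta space and group into families.

    Functions with Omega = 0 (the constants, under product inputs) have no
    delta point; they are collected in a degenerate bucket with family id -1.
    """
    rows = []
    for f in enumerate_functions(n, allow_large=allow_large):
        dx, dy, dz, om = _delta_row(f, input_dist)
        rows.append(
            (f.index(), "".join(map(str, f.digits)), dx, dy, dz, om)
        )
    entries = pd.DataFrame(
        rows,
        columns=["function_id", "digits", "delta_x", "delta_y", "delta_z", "omega"],
    )
    degenerate = entries["omega"] <= 0.0
    key = entries.loc[~degenerate, ["delta_x", "delta_y", "delta_z"]].round(
        grouping_decimals
    )
    grouped = key.groupby(["delta_x", "delta_y", "delta_z"], sort=True)
    family_ids = np.full(len(entries), -1, dtype=np.int64)
    fam_rows = []
    for fam_id, (_, idx) in enumerate(sorted(grouped.groups.items())):
        pos = np.asarray(idx, dtype=np.int64)
        family_ids[pos] = fam_id
        rep_pos = int(entries.loc[pos, "function_id"].idxmin())
        rep = int(entries.loc[rep_pos, "function_id"])
        # store the representative's unrounded coordinates (rounded values
        # are only the grouping key)
        point = entries.loc[rep_pos, ["delta_x", "delta_y", "delta_z"]]
        fam_rows.append((fam_id, *point, len(pos), rep))
    entries["family"] = family_ids
    families = pd.DataFrame(
        fam_rows,
        columns=[
            "family",
            "delta_x",
            "delta_y",
            "delta_z",
            "member_count",
            "representative_id",
        ],
    ).set_index("family")
    return FunctionAtlas(
        alphabet_size=n,
        entries=entries,
        families=families,
        degenerate_ids=tuple(entries.loc[degenerate, "function_id"]),
    )
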