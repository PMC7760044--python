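"""The Bertschinger polytope Q and its image in delta space.

Q is the set of joint distributions q(x, y, z) sharing the (X,Z) and (Y,Z)
marginals of a base distribution; only the X-Y dependence is free.  Within
each z-layer the admissible perturbations are matrices with zero row and
column sums, parameterized by a free (Nx-1) x (Ny-1) block whose last
row/column/corner are determined.  Every member of Q keeps HX, HY, HZ, HXZ
and HYZ fixed, so its delta coordinates are confined to the plane

    (c1 - c4)(deltaX - deltaY) + (c3 - c2)(1 - deltaZ) = 0

with constants c1 = HX+HY+HZ, c2 = HXZ-HX, c3 = HYZ-HY, c4 = HXZ+HYZ-HZ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .distribution import JointDistribution, shannon_profile

__all__ = [
    "QParameterization",
    "QPlane",
    "QSample",
    "parameterize",
    "feasible_interval",
    "sample_q",
    "q_plane",
    "batch_deltas",
]

MARGINAL_TOL = 1e-12
_DEGENERATE_PLANE_TOL = 1e-12


@dataclass(frozen=True)
class QParameterization:
    """Linear parameterization of all marginal-preserving perturbations.

    Parameter ``(z, i, j)`` (flattened in C order) adds ``+t`` to cell
    ``(i, j, z)``, ``-t`` to ``(i, Ny-1, z)`` and ``(Nx-1, j, z)`` and
    ``+t`` to the corner ``(Nx-1, Ny-1, z)``, so each z-layer keeps its row
    and column sums — i.e. the (X,Z) and (Y,Z) marginals — exactly.
    """

    base: JointDistribution
    basis: np.ndarray = field(init=False, repr=False)  # (n_params, Nx, Ny, Nz)

    def __post_init__(self) -> None:
        nx, ny, nz = self.base.alphabet_sizes
        if nx < 2 or ny < 2:
            raise ValueError("source alphabets must have at least two symbols")
        n_params = nz * (nx - 1) * (ny - 1)
        basis = np.zeros((n_params, nx, ny, nz))
        k = 0
        for z in range(nz):
            for i in range(nx - 1):
                for j in range(ny - 1):
                    basis[k, i, j, z] = 1.0
                    basis[k, i, ny - 1, z] = -1.0
                    basis[k, nx - 1, j, z] = -1.0
                    basis[k, nx - 1, ny - 1, z] = 1.0
                    k += 1
        basis.flags.writeable = False
        object.__setattr__(self, "basis", basis)

    @property
    def n_params(self) -> int:
        return self.basis.shape[0]

    @property
    def params_per_layer(self) -> int:
        nx, ny, _ = self.base.alphabet_sizes
        return (nx - 1) * (ny - 1)

    def tensor(self, t: np.ndarray) -> np.ndarray:
        """Raw perturbed tensor (not validated against [0, 1])."""
        t = np.asarray(t, dtype=float)
        if t.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {t.shape}")
        return self.base.values + np.tensordot(t, self.basis, axes=1)

    def distribution(self, t: np.ndarray, tol: float = 1e-12) -> JointDistribution:
        """Perturbed distribution; raises if any cell is below ``-tol``."""
        arr = self.tensor(t)
        if arr.min() < -tol:
            raise ValueError(
                f"parameters leave the polytope (min cell {arr.min():.3e})"
            )
        arr = np.clip(arr, 0.0, None)
        return JointDistribution(arr / arr.sum())

    def is_feasible(self, t: np.ndarray, tol: float = 1e-12) -> bool:
        return bool(self.tensor(t).min() >= -tol)

    @property
    def structural_zero_mask(self) -> np.ndarray:
        """Cells forced to zero in *every* member of Q.

        If a (X,Z) or (Y,Z) marginal cell is zero, every joint cell under it
        is zero throughout Q.
        """
        p_xz = self.base.marginal("XZ")
        p_yz = self.base.marginal("YZ")
        return (p_xz[:, None, :] <= 0.0) | (p_yz[None, :, :] <= 0.0)

    @property
    def direction_projector(self) -> np.ndarray:
        """Projector onto parameter directions that keep structural zeros at 0.

        The base point of a deterministic relationship typically sits on a
        vertex of Q; unprojected random directions are then almost surely
        infeasible.
        """
        mask = self.structural_zero_mask.ravel()
        k = self.n_params
        if not mask.any():
            return np.eye(k)
        m = self.basis.reshape(k, -1)[:, mask]
        u, s, _ = np.linalg.svd(m, full_matrices=False)
        rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
        return np.eye(k) - u[:, :rank] @ u[:, :rank].T

    def segment(
        self, t0: np.ndarray, direction: np.ndarray
    ) -> tuple[float, float]:
        """Exact feasible interval [lo, hi] of s for ``t0 + s * direction``.

        Only the lower cell bounds bind: the tensor total is conserved, so
        non-negative cells cannot exceed one.
        """
        v0 = self.tensor(t0).ravel()
        g = np.tensordot(np.asarray(direction, dtype=float), self.basis, axes=1).ravel()
        lo, hi = -np.inf, np.inf
        nz = np.abs(g) > 1e-15
        bound = -v0[nz] / g[nz]
        pos = g[nz] > 0
        if np.any(~pos):
            hi = float(bound[~pos].min())
        if np.any(pos):
            lo = float(bound[pos].max())
        return (min(lo, 0.0) if lo > 0 else lo, max(hi, 0.0) if hi < 0 else hi)


def parameterize(dist: JointDistribution) -> QParameterization:
    """Build the Q-set parameterization for a distribution."""
    return QParameterization(dist)


def feasible_interval(param: QParameterization, index: int) -> tuple[float, float]:
    """Closed-form feasible interval of one parameter, all others at zero."""
    if not 0 <= index < param.n_params:
        raise IndexError(f"parameter index {index} out of range")
    direction = np.zeros(param.n_params)
    direction[index] = 1.0
    lo, hi = param.segment(np.zeros(param.n_params), direction)
    # base is feasible, so the interval always contains 0
    return (min(lo, 0.0), max(hi, 0.0))


@dataclass(frozen=True)
class QPlane:
    """The plane in delta space containing the image of a Q set."""

    c1: float
    c2: float
    c3: float
    c4: float

    @property
    def coefficients(self) -> tuple[float, float]:
        """(a, b) of the implicit form a*(deltaX - deltaY) + b*(1 - deltaZ) = 0."""
        return (self.c1 - self.c4, self.c3 - self.c2)

    @property
    def is_degenerate(self) -> bool:
        a, b = self.coefficients
        return abs(a) < _DEGENERATE_PLANE_TOL and abs(b) < _DEGENERATE_PLANE_TOL

    def residual(self, delta_x: float, delta_y: float, delta_z: float) -> float:
        a, b = self.coefficients
        return a * (delta_x - delta_y) + b * (1.0 - delta_z)

    def residuals(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a, b = self.coefficients
        return a * (pts[:, 0] - pts[:, 1]) + b * (1.0 - pts[:, 2])


def q_plane(dist: JointDistribution) -> QPlane:
    """Constants of the Q-plane from the entropies invariant over Q."""
    prof = shannon_profile(dist)
    return QPlane(
        c1=prof.h_x + prof.h_y + prof.h_z,
        c2=-prof.h_x + prof.h_xz,
        c3=-prof.h_y + prof.h_yz,
        c4=-prof.h_z + prof.h_xz + prof.h_yz,
    )


@dataclass(frozen=True)
class QSample:
    """Seeded sample of Q members with their delta coordinates."""

    param: QParameterization
    parameters: np.ndarray  # (n, n_params); row 0 is the base point
    seed: int

    @property
    def tensors(self) -> np.ndarray:
        return self.param.base.values + np.tensordot(
            self.parameters, self.param.basis, axes=1
        )

    @property
    def deltas(self) -> np.ndarray:
        """(n, 3) array of delta coordinates (NaN rows where Omega ~ 0)."""
        return batch_deltas(self.tensors)[0]

    @property
    def omegas(self) -> np.ndarray:
        return batch_deltas(self.tensors)[1]

    def distributions(self) -> list[JointDistribution]:
        return [self.param.distribution(t) for t in self.parameters]

    def to_dataframe(self):
        import pandas as pd

        d, om = batch_deltas(self.tensors)
        cols = {"sample_id": np.arange(len(self.parameters))}
        for k in range(self.parameters.shape[1]):
            cols[f"t{k}"] = self.parameters[:, k]
        cols.update(
            delta_x=d[:, 0], delta_y=d[:, 1], delta_z=d[:, 2], omega=om
        )
        return pd.DataFrame(cols)


def _batch_entropy(p: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Entropies in bits of marginals over `axes` for a (n, Nx, Ny, Nz) batch."""
    m = p.sum(axis=tuple(ax for ax in (1, 2, 3) if ax not in axes)) if len(axes) < 3 else p
    m = m.reshape(m.shape[0], -1)
    m = np.clip(m, 0.0, None)
    return -xlogy(m, m).sum(axis=1) / np.log(2.0)


def batch_deltas(tensors: np.ndarray, omega_tol: float = 1e-12):
    """Delta coordinates for a batch of (n, Nx, Ny, Nz) probability tensors.

    Returns ``(deltas, omegas)`` where rows of ``deltas`` are NaN when Omega
    is below ``omega_tol``.
    """
    p = np.asarray(tensors, dtype=float)
    if p.ndim == 3:
        p = p[None]
    h_x = _batch_entropy(p, (1,))
    h_y = _batch_entropy(p, (2,))
    h_z = _batch_entropy(p, (3,))
    h_xy = _batch_entropy(p, (1, 2))
    h_xz = _batch_entropy(p, (1, 3))
    h_yz = _batch_entropy(p, (2, 3))
    h_xyz = _batch_entropy(p, (1, 2, 3))
    omega = h_x + h_y + h_z - h_xyz
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.stack(
            [
                (-h_x + h_xy + h_xz - h_xyz) / omega,
                (-h_y + h_xy + h_yz - h_xyz) / omega,
                (-h_z + h_xz + h_yz - h_xyz) / omega,
            ],
            axis=1,
        )
    d[omega < omega_tol] = np.nan
    return d, omega


def _sinkhorn_layer(
    w: np.ndarray, r: np.ndarray, c: np.ndarray, n_iter: int = 300
) -> np.ndarray:
    """Scale a positive seed matrix to given row/column sums (IPF)."""
    m = w * np.outer(r > 0, c > 0)
    for _ in range(n_iter):
        rs = m.sum(axis=1)
        m = np.where(rs[:, None] > 0, m * np.divide(
            r, rs, out=np.ones_like(r), where=rs > 0)[:, None], 0.0)
        cs = m.sum(axis=0)
        m = np.where(cs[None, :] > 0, m * np.divide(
            c, cs, out=np.ones_like(c), where=cs > 0)[None, :], 0.0)
        if abs(m.sum(axis=1) - r).max() < 1e-14:
            break
    return m


def _transport_candidate(
    param: QParameterization, rng: np.random.Generator
) -> np.ndarray:
    """A feasible parameter vector from per-layer transport scaling.

    Each z-layer of a Q member is a non-negative matrix with prescribed row
    sums p(x,z) and column sums p(y,z); scaling a random positive seed to
    those marginals (Sinkhorn iteration) lands strictly inside the layer's
    transportation polytope.
    """
    base = param.base.values
    nx, ny, nz = base.shape
    p_xz = param.base.marginal("XZ")
    p_yz = param.base.marginal("YZ")
    tensor = np.empty_like(base)
    for z in range(nz):
        seed = rng.exponential(size=(nx, ny))
        tensor[:, :, z] = _sinkhorn_layer(seed, p_xz[:, z], p_yz[:, z])
    diff = tensor - base
    return diff[: nx - 1, : ny - 1, :].transpose(2, 0, 1).ravel()


def sample_q(
    param: QParameterization,
    n_samples: int,
    seed: int,
    *,
    n_sweeps: int = 10,
) -> QSample:
    """Draw feasible Q members; sample 0 is always the base distribution.

    Candidate parameter vectors come from uniform rejection over the product
    of single-parameter feasible intervals; when those boxes are degenerate
    or acceptance falls below 0.1% (the base point of a deterministic
    relationship is a vertex of Q, where every single-parameter interval can
    collapse), candidates come from per-layer transport scaling instead.
    Each candidate is then refined by ``n_sweeps`` hit-and-run steps —
    uniform draws on the exact feasible segment along random directions
    projected to preserve structural zeros.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    k = param.n_params
    boxes = np.array([feasible_interval(param, i) for i in range(k)])
    free = (boxes[:, 1] - boxes[:, 0]) > 1e-14
    projector = param.direction_projector

    n_accepted, n_tried = 0, 0
    accepted: list[np.ndarray] = []
    fallback = not free.any()
    while len(accepted) < n_samples - 1:
        if not fallback:
            cand = np.where(
                free, rng.uniform(boxes[:, 0], boxes[:, 1], size=k), 0.0
            )
            n_tried += 1
            if param.is_feasible(cand):
                accepted.append(cand)
                n_accepted += 1
            if n_tried >= 1000 and n_accepted / n_tried < 1e-3:
                fallback = True
        else:
            accepted.append(_transport_candidate(param, rng))

    out = np.zeros((n_samples, k))
    for row, cand in enumerate(accepted, start=1):
        t = cand.copy()
        for _ in range(n_sweeps):
            direction = projector @ rng.standard_normal(k)
            norm = np.linalg.norm(direction)
            if norm < 1e-12:
                continue
            direction /= norm
            lo, hi = param.segment(t, direction)
            if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo < 1e-13:
                continue
            t = t + rng.uniform(lo, hi) * direction
        out[row] = t
    return QSample(param=param, parameters=out, seed=seed)
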