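"""Identities linking delta coordinates to PID components.

The decomposition identities and the delta inversion formulas combine into
three linear relations ("bridge identities") that hold for *any* PID
solution, because their left-hand sides depend only on the distribution:

    (Omega/2)(+dX + dY - dZ + 1) = UX + UY + R + S
    (Omega/2)(-dX + dY - dZ + 1) = UX + R
    (Omega/2)(+dX - dY - dZ + 1) = UY + R

from which S - R = (Omega/2)(dX + dY + dZ - 1) = II(X,Y,Z) and
UX - UY = Omega (dY - dX).  These are computed here from the coordinates
alone — never from solver output — so checking a solver against them is a
genuine cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .delta import DeltaCoordinates, deltas, plane_distance
from .distribution import JointDistribution

__all__ = [
    "PIDComponents",
    "ConsistencyReport",
    "s_minus_r",
    "ux_minus_uy",
    "check_consistency",
]


@dataclass(frozen=True)
class PIDComponents:
    """Solver-tagged PID components in bits."""

    ux: float
    uy: float
    r: float
    s: float
    solver: str = "external"

    @property
    def total(self) -> float:
        return self.ux + self.uy + self.r + self.s

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.ux, self.uy, self.r, self.s)


def s_minus_r(delta: DeltaCoordinates) -> float:
    """S - R from coordinates alone; equals the interaction information."""
    om = delta.omega
    return 0.5 * om * (delta.delta_x + delta.delta_y + delta.delta_z - 1.0)


def ux_minus_uy(delta: DeltaCoordinates) -> float:
    """UX - UY from coordinates alone: Omega * (deltaY - deltaX)."""
    return delta.omega * (delta.delta_y - delta.delta_x)


@dataclass(frozen=True)
class ConsistencyReport:
    """Residuals of every bridge identity for one (distribution, PID) pair."""

    residuals: dict[str, float]
    tol: float

    @property
    def max_residual(self) -> float:
        return max(abs(v) for v in self.residuals.values())

    @property
    def passed(self) -> bool:
        return self.max_residual <= self.tol


def check_consistency(
    pid: PIDComponents, dist: JointDistribution, tol: float = 1e-6
) -> ConsistencyReport:
    """Residuals of the three bridge rows, the difference identities, and
    the plane-distance form, for a PID claimed to describe ``dist``."""
    d = deltas(dist)
    om, dx, dy, dz = d.omega, d.delta_x, d.delta_y, d.delta_z
    dist_d = plane_distance(d)
    residuals = {
        "total": 0.5 * om * (dx + dy - dz + 1.0) - pid.total,
        "ux_plus_r": 0.5 * om * (-dx + dy - dz + 1.0) - (pid.ux + pid.r),
        "uy_plus_r": 0.5 * om * (dx - dy - dz + 1.0) - (pid.uy + pid.r),
        "s_minus_r": s_minus_r(d) - (pid.s - pid.r),
        "ux_minus_uy": ux_minus_uy(d) - (pid.ux - pid.uy),
        "plane_form": 0.5 * om * (2.0 - dist_d) - pid.total,
    }
    return ConsistencyReport(residuals=residuals, tol=tol)
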