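"""Information-delta coordinates and the function-plane geometry.

The raw delta of a variable is the drop in co-information when that variable
joins the pair of others; each equals minus a conditional mutual information
(e.g. the raw Z-delta is ``-I(X:Y|Z)``).  Normalizing by the
multi-information Omega = HX + HY + HZ - HXYZ gives dimensionless
coordinates (deltaX, deltaY, deltaZ) in [0, 1] for most distributions.
Deterministic relationships Z = f(X, Y) with independent inputs land on the
plane deltaZ = deltaX + deltaY - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .distribution import JointDistribution, mutual_information, shannon_profile

__all__ = [
    "DeltaCoordinates",
    "UndefinedDeltaError",
    "deltas",
    "plane_distance",
    "mutual_informations_from_deltas",
]

#: Omega below this raises (coordinates undefined)
OMEGA_UNDEFINED = 1e-12
#: Omega below this only warns (coordinates ill-conditioned)
OMEGA_ILL_CONDITIONED = 1e-6

_CROSSCHECK_TOL = 1e-10


class UndefinedDeltaError(ValueError):
    """Raised when Omega is (numerically) zero so delta coordinates are undefined."""


@dataclass(frozen=True)
class DeltaCoordinates:
    """Normalized delta coordinates with their raw (bit-valued) counterparts."""

    delta_x: float
    delta_y: float
    delta_z: float
    omega: float

    @property
    def raw_delta_x(self) -> float:
        """Raw X-delta in bits: -I(Y:Z|X)."""
        return -self.delta_x * self.omega

    @property
    def raw_delta_y(self) -> float:
        return -self.delta_y * self.omega

    @property
    def raw_delta_z(self) -> float:
        return -self.delta_z * self.omega

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_x, self.delta_y, self.delta_z)


def deltas(dist: JointDistribution) -> DeltaCoordinates:
    """Delta coordinates of a joint distribution.

    Each normalized delta is a conditional mutual information over Omega:
    deltaX = I(Y:Z|X)/Omega and cyclically.  The equivalent four-entropy
    alternating-sum form is evaluated as an internal cross-check.

    Raises
    ------
    UndefinedDeltaError
        If Omega is numerically zero (fully independent variables).
    """
    prof = shannon_profile(dist)
    omega = prof.omega
    if omega < OMEGA_UNDEFINED:
        raise UndefinedDeltaError(
            f"multi-information Omega={omega:.3e} bits is zero; "
            "delta coordinates are undefined for independent variables"
        )
    if omega < OMEGA_ILL_CONDITIONED:
        warnings.warn(
            f"Omega={omega:.3e} bits is tiny; delta coordinates are "
            "ill-conditioned ratios",
            RuntimeWarning,
            stacklevel=2,
        )
    d_x = mutual_information(dist, "Y", "Z", "X") / omega
    d_y = mutual_information(dist, "X", "Z", "Y") / omega
    d_z = mutual_information(dist, "X", "Y", "Z") / omega

    # entropy-form cross-check, e.g. deltaX = (-HX+HXY+HXZ-HXYZ)/Omega
    ent_x = (-prof.h_x + prof.h_xy + prof.h_xz - prof.h_xyz) / omega
    ent_y = (-prof.h_y + prof.h_xy + prof.h_yz - prof.h_xyz) / omega
    ent_z = (-prof.h_z + prof.h_xz + prof.h_yz - prof.h_xyz) / omega
    resid = max(abs(d_x - ent_x), abs(d_y - ent_y), abs(d_z - ent_z))
    if resid > _CROSSCHECK_TOL / min(omega, 1.0):
        raise AssertionError(
            f"conditional-MI and entropy forms of delta disagree by {resid:.3e}"
        )
    return DeltaCoordinates(delta_x=d_x, delta_y=d_y, delta_z=d_z, omega=omega)


def plane_distance(delta: DeltaCoordinates) -> float:
    """Signed distance above the function plane: deltaZ - deltaX - deltaY + 1.

    Zero for any deterministic Z = f(X, Y) with independent inputs.
    """
    return delta.delta_z - delta.delta_x - delta.delta_y + 1.0


def mutual_informations_from_deltas(
    delta: DeltaCoordinates,
) -> tuple[float, float, float]:
    """Invert the coordinates back to (I(Z:XY), I(Z:X), I(Z:Y)) in bits."""
    om, dx, dy, dz = delta.omega, delta.delta_x, delta.delta_y, delta.delta_z
    i_z_xy = 0.5 * om * (dx + dy - dz + 1.0)
    i_zx = 0.5 * om * (-dx - dz + dy + 1.0)
    i_zy = 0.5 * om * (-dy - dz + dx + 1.0)
    return (i_z_xy, i_zx, i_zy)
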