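"""Model/results interface for three-variable information decomposition.

:class:`Triad` wraps a joint distribution of two sources and a target, built
from counts, raw observations, a dataframe, or a generating function.  Its
:meth:`Triad.fit` runs the requested PID solver(s) and returns a
:class:`TriadResults` carrying the Shannon profile, delta coordinates, PID
components, bridge-identity residuals and an optional library match, with a
printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import broja as _broja
from . import pointwise as _pointwise
from .bridge import ConsistencyReport, PIDComponents, check_consistency
from .delta import DeltaCoordinates, UndefinedDeltaError, deltas, plane_distance
from .distribution import (
    CountTable,
    JointDistribution,
    ShannonProfile,
    normalize_counts,
    shannon_profile,
)
from .functions import DiscreteFunction, function_to_distribution
from .library import FunctionLibrary, QueryResult, query as _query

__all__ = ["Triad", "TriadResults"]


class Triad:
    """A discrete (X, Y -> Z) triplet ready for information decomposition.

    Parameters
    ----------
    dist
        The joint distribution p(x, y, z).
    names
        Optional display names for the two sources and the target.
    """

    def __init__(
        self,
        dist: JointDistribution,
        names: tuple[str, str, str] = ("X", "Y", "Z"),
    ):
        self.dist = dist
        self.names = names

    # ---------------------------------------------------------------- build
    @classmethod
    def from_counts(
        cls,
        counts: CountTable | dict[tuple[int, int, int], int],
        alphabet_sizes: tuple[int, int, int] | None = None,
        **kw,
    ) -> "Triad":
        if isinstance(counts, dict):
            counts = CountTable.from_mapping(counts)
        if alphabet_sizes is None:
            alphabet_sizes = tuple(
                max(rec[i] for rec in counts.records) + 1 for i in range(3)
            )  # type: ignore[assignment]
        return cls(normalize_counts(counts, alphabet_sizes), **kw)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        x: str = "x",
        y: str = "y",
        z: str = "z",
        count: str | None = None,
        alphabet_sizes: tuple[int, int, int] | None = None,
    ) -> "Triad":
        """Build from per-observation rows, or per-cell rows if ``count`` names
        a column of multiplicities."""
        weights = data[count] if count is not None else np.ones(len(data), dtype=int)
        table: dict[tuple[int, int, int], int] = {}
        for xi, yi, zi, w in zip(data[x], data[y], data[z], weights):
            key = (int(xi), int(yi), int(zi))
            table[key] = table.get(key, 0) + int(w)
        return cls.from_counts(table, alphabet_sizes, names=(x, y, z))

    @classmethod
    def from_function(
        cls, f: DiscreteFunction, input_dist: np.ndarray | None = None, **kw
    ) -> "Triad":
        return cls(function_to_distribution(f, input_dist), **kw)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        solver: str = "both",
        *,
        library: FunctionLibrary | None = None,
        k: int = 3,
        seed: int = 0,
        broja_opts: dict | None = None,
    ) -> "TriadResults":
        """Estimate the PID with the chosen solver(s).

        solver is ``"broja"`` (optimization over the marginal-preserving
        polytope), ``"ppid"`` (pointwise specificity/ambiguity), or
        ``"both"``.  If a ``library`` is given and delta coordinates are
        defined, the nearest function families are attached.
        """
        if solver not in ("broja", "ppid", "both"):
            raise ValueError(f"unknown solver {solver!r}")
        profile = shannon_profile(self.dist)
        try:
            delta = deltas(self.dist)
        except UndefinedDeltaError:
            delta = None
        pid: dict[str, PIDComponents] = {}
        diagnostics: dict[str, object] = {}
        if solver in ("broja", "both"):
            sol = _broja.solve(self.dist, seed=seed, **(broja_opts or {}))
            pid["broja"] = PIDComponents(*sol.as_tuple(), solver="broja")
            diagnostics["broja"] = sol.diagnostics
        if solver in ("ppid", "both"):
            psol = _pointwise.solve(self.dist)
            pid["ppid"] = PIDComponents(*psol.as_tuple(), solver="ppid")
            diagnostics["ppid"] = {
                "rmin_plus": psol.rmin_plus,
                "rmin_minus": psol.rmin_minus,
            }
        consistency = {
            name: check_consistency(components, self.dist)
            for name, components in pid.items()
            if delta is not None
        }
        match = None
        if library is not None and delta is not None:
            match = _query(library, delta, k=k)
        return TriadResults(
            model=self,
            profile=profile,
            delta=delta,
            pid=pid,
            consistency=consistency,
            library_match=match,
            diagnostics=diagnostics,
        )


@dataclass(frozen=True)
class TriadResults:
    """Fitted decomposition of one triplet."""

    model: Triad
    profile: ShannonProfile
    delta: Optional[DeltaCoordinates]
    pid: dict[str, PIDComponents]
    consistency: dict[str, ConsistencyReport]
    library_match: Optional[QueryResult] = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {
            "names": list(self.model.names),
            "alphabet_sizes": list(self.model.dist.alphabet_sizes),
            "profile": {
                k: getattr(self.profile, k)
                for k in (
                    "h_x", "h_y", "h_z", "h_xy", "h_xz", "h_yz", "h_xyz",
                    "i_zx", "i_zy", "i_xy", "i_z_xy", "i_y_xz", "i_x_yz",
                    "co_information", "interaction_information", "omega",
                )
            },
        }
        if self.delta is None:
            out["delta"] = None
        else:
            out["delta"] = {
                "delta_x": self.delta.delta_x,
                "delta_y": self.delta.delta_y,
                "delta_z": self.delta.delta_z,
                "omega": self.delta.omega,
                "plane_distance": plane_distance(self.delta),
            }
        out["pid"] = {
            name: {"ux": c.ux, "uy": c.uy, "r": c.r, "s": c.s}
            for name, c in self.pid.items()
        }
        out["consistency"] = {
            name: {"max_residual": rep.max_residual, "passed": rep.passed}
            for name, rep in self.consistency.items()
        }
        if self.library_match is not None:
            out["library_match"] = [
                {
                    "family_id": m.family_id,
                    "distance": m.distance,
                    "representative": "".join(map(str, m.representative.digits)),
                    "pid": {
                        s: {"ux": c.ux, "uy": c.uy, "r": c.r, "s": c.s}
                        for s, c in m.pid.items()
                    },
                }
                for m in self.library_match.matches
            ]
        return out

    def summary(self) -> str:
        """Human-readable report (4-decimal rounding)."""
        x, y, z = self.model.names
        p = self.profile
        lines = [
            "Information decomposition of "
            f"({x}, {y}) -> {z}   alphabet {self.model.dist.alphabet_sizes}",
            "=" * 64,
            f"I({z}:{x})      {p.i_zx: .4f}   I({z}:{y})   {p.i_zy: .4f}   "
            f"I({z}:{x},{y}) {p.i_z_xy: .4f}  [bits]",
            f"II           {p.interaction_information: .4f}   "
            f"Omega     {p.omega: .4f}",
        ]
        if self.delta is not None:
            d = self.delta
            lines.append(
                f"delta         ({d.delta_x: .4f}, {d.delta_y: .4f}, "
                f"{d.delta_z: .4f})   plane distance {plane_distance(d): .4f}"
            )
        else:
            lines.append("delta         undefined (Omega = 0: independent variables)")
        lines.append("-" * 64)
        lines.append(f"{'solver':8s} {'UX':>9s} {'UY':>9s} {'R':>9s} {'S':>9s}")
        for name, c in self.pid.items():
            lines.append(
                f"{name:8s} {c.ux:9.4f} {c.uy:9.4f} {c.r:9.4f} {c.s:9.4f}"
            )
        for name, rep in self.consistency.items():
            status = "ok" if rep.passed else "FAIL"
            lines.append(
                f"bridge identities [{name}]: max residual "
                f"{rep.max_residual:.2e} ({status})"
            )
        if self.library_match is not None:
            best = self.library_match.best
            lines.append(
                f"nearest family: #{best.family_id} "
                f"(table {''.join(map(str, best.representative.digits))}, "
                f"distance {best.distance:.4f})"
            )
        return "\n".join(lines)
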