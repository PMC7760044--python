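"""Function-family library and nearest-family lookup.

The two-step analysis procedure for empirical triples: (1) build, once, a
library holding — for every function family of the chosen alphabet — the
representative function, its base delta point, the plane its Q set spans, a
seeded sample of that Q set's delta cloud, and the PID components from both
solvers; (2) match the delta coordinates of observed data to the family
with the nearest stored manifold, which immediately yields a candidate
generating function and its PID.

Matching uses the 4-dimensional point (deltaX, deltaY, deltaZ, Omega):
distinct families can share a delta point while differing sharply in
multi-information, and Omega is free to the observer.  Each family's stored
manifold is the union of its Q delta-cloud (tolerating source dependence
such as linkage disequilibrium) and a deterministic *corruption sheet* —
the exact coordinates of the representative function under a grid of
output-noise levels and source-coupling strengths.  Real measurement noise
pushes observations off every Q manifold; the sheet restores a nearby
on-manifold point for the generating family without any probabilistic
noise calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import broja, pointwise
from .bridge import PIDComponents
from .delta import DeltaCoordinates
from .functions import DiscreteFunction, build_atlas, function_to_distribution
from .qset import QPlane, batch_deltas, parameterize, q_plane, sample_q

__all__ = ["LibraryEntry", "FunctionLibrary", "QueryMatch", "QueryResult", "build", "query"]

_FORMAT_VERSION = 2

#: default output-noise levels of the corruption sheet
NOISE_GRID = tuple(np.linspace(0.0, 0.2, 21))
#: default source-coupling strengths of the corruption sheet
COUPLING_GRID = tuple(np.linspace(0.0, 0.4, 17))


def corruption_sheet(
    f: DiscreteFunction,
    noise_grid=NOISE_GRID,
    coupling_grid=COUPLING_GRID,
) -> np.ndarray:
    """Exact (delta, Omega) coordinates of f under noise and coupling.

    For coupling rho the sources follow the uniform/diagonal mixture
    p(x,y) = (1-rho)/N^2 + rho [x==y]/N; for noise eps the output symbol is
    replaced uniformly with probability eps, i.e. the joint becomes
    (1-eps) q + eps * q_XY x u_Z.  Returns an (m, 4) array; rows whose
    Omega vanishes are dropped.
    """
    from .synthetic import coupled_input_distribution

    n = f.alphabet_size
    bases = np.array(
        [
            function_to_distribution(f, coupled_input_distribution(n, rho)).values
            for rho in coupling_grid
        ]
    )
    q_xy = bases.sum(axis=3, keepdims=True)
    eps = np.asarray(noise_grid)[:, None, None, None, None]
    sheets = (1.0 - eps) * bases[None] + eps * q_xy[None] / n
    tensors = sheets.reshape(-1, n, n, n)
    d, om = batch_deltas(tensors)
    ok = ~np.isnan(d).any(axis=1)
    return np.column_stack([d[ok], om[ok]])


@dataclass(frozen=True)
class LibraryEntry:
    family_id: int
    representative: DiscreteFunction
    base_delta: tuple[float, float, float]
    omega: float
    plane: QPlane
    cloud: np.ndarray  # (n_samples, 3) Q delta coordinates; row 0 is base
    cloud_omega: np.ndarray  # (n_samples,) Omega of each Q sample
    sheet: np.ndarray  # (m, 4) corruption-sheet coordinates (delta, Omega)
    member_count: int
    pid: dict[str, PIDComponents]  # solver name -> components

    def manifold(self) -> np.ndarray:
        """(n + m, 4) union of the Q cloud and the corruption sheet."""
        cloud4 = np.column_stack([self.cloud, self.cloud_omega])
        return np.vstack([cloud4, self.sheet]) if len(self.sheet) else cloud4


@dataclass(frozen=True)
class QueryMatch:
    family_id: int
    distance: float
    plane_residual: float
    representative: DiscreteFunction
    pid: dict[str, PIDComponents]


@dataclass(frozen=True)
class QueryResult:
    query_delta: tuple[float, float, float]
    matches: tuple[QueryMatch, ...]

    @property
    def best(self) -> QueryMatch:
        return self.matches[0]


@dataclass(frozen=True)
class FunctionLibrary:
    alphabet_size: int
    entries: tuple[LibraryEntry, ...]
    samples_per_family: int
    seed: int

    def entry(self, family_id: int) -> LibraryEntry:
        for e in self.entries:
            if e.family_id == family_id:
                return e
        raise KeyError(f"no family {family_id} in library")

    # -- persistence: one self-describing JSON plus a TSV cloud table -------

    def save(self, basepath: str | Path) -> tuple[Path, Path]:
        base = Path(basepath)
        json_path = base.with_suffix(".json")
        cloud_path = base.with_suffix(".cloud.tsv")
        meta = {
            "format": "deltapid-function-library",
            "version": _FORMAT_VERSION,
            "alphabet_size": self.alphabet_size,
            "samples_per_family": self.samples_per_family,
            "seed": self.seed,
            "entries": [
                {
                    "family_id": e.family_id,
                    "representative_digits": list(map(int, e.representative.digits)),
                    "base_delta": list(e.base_delta),
                    "omega": e.omega,
                    "plane": asdict(e.plane),
                    "member_count": e.member_count,
                    "pid": {
                        solver: {
                            "ux": c.ux, "uy": c.uy, "r": c.r, "s": c.s,
                        }
                        for solver, c in e.pid.items()
                    },
                }
                for e in self.entries
            ],
        }
        json_path.write_text(json.dumps(meta, indent=1))
        rows = []
        for e in self.entries:
            for i, (pt, om) in enumerate(zip(e.cloud, e.cloud_omega)):
                rows.append((e.family_id, "q", i, *pt, om))
            for i, pt in enumerate(e.sheet):
                rows.append((e.family_id, "sheet", i, *pt))
        pd.DataFrame(
            rows,
            columns=[
                "family", "kind", "sample_id",
                "delta_x", "delta_y", "delta_z", "omega",
            ],
        ).to_csv(cloud_path, sep="\t", index=False)
        return json_path, cloud_path

    @classmethod
    def load(cls, basepath: str | Path) -> "FunctionLibrary":
        base = Path(basepath)
        meta = json.loads(base.with_suffix(".json").read_text())
        if meta.get("format") != "deltapid-function-library":
            raise ValueError(f"{base}: not a function-library archive")
        clouds = pd.read_csv(base.with_suffix(".cloud.tsv"), sep="\t")
        cols = ["delta_x", "delta_y", "delta_z", "omega"]
        grouped_q = {
            fam: g[cols].to_numpy()
            for fam, g in clouds[clouds["kind"] == "q"].groupby("family")
        }
        grouped_sheet = {
            fam: g[cols].to_numpy()
            for fam, g in clouds[clouds["kind"] == "sheet"].groupby("family")
        }
        n = meta["alphabet_size"]
        entries = []
        for rec in meta["entries"]:
            digits = np.array(rec["representative_digits"], dtype=np.int64)
            q4 = grouped_q[rec["family_id"]]
            entries.append(
                LibraryEntry(
                    family_id=rec["family_id"],
                    representative=DiscreteFunction(digits.reshape(n, n)),
                    base_delta=tuple(rec["base_delta"]),
                    omega=rec["omega"],
                    plane=QPlane(**rec["plane"]),
                    cloud=q4[:, :3],
                    cloud_omega=q4[:, 3],
                    sheet=grouped_sheet.get(
                        rec["family_id"], np.empty((0, 4))
                    ),
                    member_count=rec["member_count"],
                    pid={
                        solver: PIDComponents(solver=solver, **c)
                        for solver, c in rec["pid"].items()
                    },
                )
            )
        return cls(
            alphabet_size=n,
            entries=tuple(entries),
            samples_per_family=meta["samples_per_family"],
            seed=meta["seed"],
        )


def build(
    n: int,
    input_dist: np.ndarray | None = None,
    samples_per_family: int = 200,
    seed: int = 0,
    *,
    solvers: tuple[str, ...] = ("broja", "ppid"),
    broja_opts: dict | None = None,
    noise_grid=NOISE_GRID,
    coupling_grid=COUPLING_GRID,
) -> FunctionLibrary:
    """Build the full library for alphabet size ``n`` (one entry per family).

    Deterministic for a fixed seed; per-family Q samples use independent
    seeds spawned from ``seed``.
    """
    atlas = build_atlas(n, input_dist)
    rng = np.random.default_rng(seed)
    fam_seeds = rng.integers(0, 2**31, size=atlas.n_families)
    entries = []
    for fam_id in atlas.families.index:
        rep = atlas.representative(fam_id)
        dist = function_to_distribution(rep, input_dist)
        fam_seed = int(fam_seeds[fam_id])
        sample = sample_q(parameterize(dist), samples_per_family, seed=fam_seed)
        cloud4, omegas = batch_deltas(sample.tensors)
        keep = ~np.isnan(cloud4).any(axis=1)
        cloud = cloud4[keep]
        cloud_omega = omegas[keep]
        sheet = corruption_sheet(rep, noise_grid, coupling_grid)
        pid: dict[str, PIDComponents] = {}
        if "broja" in solvers:
            sol = broja.solve(dist, seed=fam_seed, **(broja_opts or {}))
            pid["broja"] = PIDComponents(*sol.as_tuple(), solver="broja")
        if "ppid" in solvers:
            psol = pointwise.solve(dist)
            pid["ppid"] = PIDComponents(*psol.as_tuple(), solver="ppid")
        row = atlas.families.loc[fam_id]
        entries.append(
            LibraryEntry(
                family_id=int(fam_id),
                representative=rep,
                base_delta=(
                    float(row["delta_x"]), float(row["delta_y"]), float(row["delta_z"]),
                ),
                omega=float(atlas.entries.loc[
                    atlas.entries["function_id"] == row["representative_id"], "omega"
                ].iloc[0]),
                plane=q_plane(dist),
                cloud=cloud,
                cloud_omega=cloud_omega,
                sheet=sheet,
                member_count=int(row["member_count"]),
                pid=pid,
            )
        )
    return FunctionLibrary(
        alphabet_size=n,
        entries=tuple(entries),
        samples_per_family=samples_per_family,
        seed=seed,
    )


def query(
    library: FunctionLibrary,
    observed: DeltaCoordinates | tuple,
    k: int = 5,
) -> QueryResult:
    """Rank families by Euclidean distance from the observed point to the
    nearest point of each family's stored manifold (Q cloud + sheet).

    A :class:`DeltaCoordinates` (or 4-tuple) is matched in (delta, Omega)
    space — Omega in bits, on the same O(1) scale as the deltas; a 3-tuple
    is matched on the delta components alone.  Ties are broken by the
    point-to-plane distance of the family's Q plane, then by family id.
    """
    if not library.entries:
        raise ValueError("library is empty")
    if isinstance(observed, DeltaCoordinates):
        point = np.array([*observed.as_tuple(), observed.omega])
    else:
        point = np.asarray(observed, dtype=float)
    n_dim = point.shape[0]
    if n_dim not in (3, 4):
        raise ValueError("observed point must have 3 or 4 components")
    scored = []
    for e in library.entries:
        dists = np.linalg.norm(e.manifold()[:, :n_dim] - point, axis=1)
        cloud_dist = float(dists.min())
        a, b = e.plane.coefficients
        norm = np.linalg.norm([a, -a, -b])
        plane_resid = (
            abs(e.plane.residual(*point[:3])) / norm if norm > 1e-12 else np.inf
        )
        scored.append((cloud_dist, plane_resid, e.family_id, e))
    scored.sort(key=lambda rec: rec[:3])
    matches = tuple(
        QueryMatch(
            family_id=e.family_id,
            distance=cd,
            plane_residual=pr,
            representative=e.representative,
            pid=e.pid,
        )
        for cd, pr, _, e in scored[: max(1, k)]
    )
    return QueryResult(query_delta=tuple(point), matches=matches)
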