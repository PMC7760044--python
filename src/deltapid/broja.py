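"""Bertschinger-style PID by constrained optimization over the Q polytope.

The four estimators are variational:

    UX = min over Q of I(Z:X|Y)          UY = min over Q of I(Z:Y|X)
    R  = max over Q of CI(X,Y,Z)         S  = I(Z:XY) - min over Q of I(Z:XY)

where I(Z:XY) outside the optimization is taken at the observed
distribution.  Each objective is a sum of marginal entropies and is convex
over the (convex) polytope Q, so multistart local optimization with
analytic gradients suffices; a derivative-free random-direction line-search
polish guards against flat boundary faces, where entropy gradients blow up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .distribution import JointDistribution, mutual_information, shannon_profile
from .qset import QParameterization, parameterize, sample_q

__all__ = ["BrojaSolution", "BrojaConvergenceError", "solve", "objective_profile"]

_LN2 = np.log(2.0)
#: floor for probabilities inside logs (entropy gradients diverge at 0)
_P_FLOOR = 1e-18
#: components more negative than this raise; within it they are clamped to 0
_CLAMP = 1e-7


class BrojaConvergenceError(RuntimeError):
    """Optimizer failed its consistency post-conditions; best bounds attached."""

    def __init__(self, message: str, best: dict[str, float]):
        super().__init__(f"{message}; best bounds: {best}")
        self.best = best


# Each objective is sum_k sign_k * H(marginal over axes_k), axes in (x,y,z)=(0,1,2).
_OBJECTIVES = {
    # I(Z:X|Y) = H(XY) + H(YZ) - H(XYZ) - H(Y)
    "i_zx_given_y": (((0, 1), 1.0), ((1, 2), 1.0), ((0, 1, 2), -1.0), ((1,), -1.0)),
    # I(Z:Y|X) = H(XY) + H(XZ) - H(XYZ) - H(X)
    "i_zy_given_x": (((0, 1), 1.0), ((0, 2), 1.0), ((0, 1, 2), -1.0), ((0,), -1.0)),
    # -CI = -(HX+HY+HZ-HXY-HXZ-HYZ+HXYZ)
    "neg_ci": (
        ((0,), -1.0), ((1,), -1.0), ((2,), -1.0),
        ((0, 1), 1.0), ((0, 2), 1.0), ((1, 2), 1.0),
        ((0, 1, 2), -1.0),
    ),
    # I(Z:XY) = H(XY) + H(Z) - H(XYZ)
    "i_z_xy": (((0, 1), 1.0), ((2,), 1.0), ((0, 1, 2), -1.0)),
}


def _objective_and_grad(terms):
    """Build f(tensor) -> (value_bits, gradient_tensor) for an entropy sum."""

    def fun(p: np.ndarray) -> tuple[float, np.ndarray]:
        val = 0.0
        grad = np.zeros_like(p)
        for axes, sign in terms:
            drop = tuple(ax for ax in range(3) if ax not in axes)
            m = p.sum(axis=drop) if drop else p
            mc = np.maximum(m, _P_FLOOR)
            val += sign * float(-(m * np.log2(mc)).sum())
            g = -(np.log2(mc) + 1.0 / _LN2)
            # broadcast marginal gradient back over the dropped axes
            shape = [1, 1, 1]
            for ax in axes:
                shape[ax] = p.shape[ax]
            grad += sign * g.reshape(shape)
        return val, grad

    return fun


_OBJ_FUNS = {name: _objective_and_grad(terms) for name, terms in _OBJECTIVES.items()}


def _evaluate(name: str, p: np.ndarray) -> float:
    return _OBJ_FUNS[name](p)[0]


def _minimize_one(
    param: QParameterization,
    name: str,
    starts: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    n_polish: int,
) -> tuple[float, np.ndarray, dict]:
    """Minimize one entropy-sum objective over Q; returns (value, t, info)."""
    fun_grad = _OBJ_FUNS[name]
    k = param.n_params
    basis_flat = param.basis.reshape(k, -1)
    # optimize inside the subspace preserving structural zeros: the
    # remaining constraints are pure inequalities
    proj = param.direction_projector

    def f(u):
        t = proj @ u
        p = param.tensor(t)
        val, grad = fun_grad(np.clip(p, 0.0, None))
        return val, proj @ (basis_flat @ grad.ravel())

    cons_jac = (proj @ basis_flat).T

    constraints = [
        {
            "type": "ineq",
            "fun": lambda u: param.tensor(proj @ u).ravel(),
            "jac": lambda u: cons_jac,
        }
    ]
    def run_slsqp(t0):
        res = minimize(
            f,
            proj @ t0,
            jac=True,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": 300, "ftol": tol},
        )
        t_res = proj @ res.x
        return t_res, _evaluate(name, np.clip(param.tensor(t_res), 0.0, None))

    best_val, best_t = np.inf, np.zeros(k)
    results = []
    for t0 in starts:
        # keep the start itself as a candidate: SLSQP can walk away from a
        # near-optimal warm start when boundary gradients blow up
        t0 = proj @ np.asarray(t0)
        val0 = _evaluate(name, np.clip(param.tensor(t0), 0.0, None))
        if val0 < best_val and param.is_feasible(t0, tol=1e-9):
            best_val, best_t = val0, t0
        t_res, val = run_slsqp(t0)
        results.append(val)
        if val < best_val and param.is_feasible(t_res, tol=1e-9):
            best_val, best_t = val, t_res

    # Iterative derivative-free polish: exact line searches along projected
    # coordinate axes and fresh random directions (single parameters may all
    # be pinned by zero cells while combined moves stay feasible), with an
    # SLSQP restart after each improving sweep.  The objective is convex, so
    # random feasible-cone directions escape any stall point with positive
    # probability per round.
    t = best_t.copy()
    if not np.isfinite(best_val):
        best_val = _evaluate(name, np.clip(param.tensor(t), 0.0, None))
    axes = [
        row / np.linalg.norm(row) for row in proj if np.linalg.norm(row) > 1e-8
    ]
    for _ in range(6):
        round_start = best_val
        directions = list(axes)
        for _ in range(n_polish):
            d = proj @ rng.standard_normal(k)
            norm = np.linalg.norm(d)
            if norm > 1e-12:
                directions.append(d / norm)
        for d in directions:
            lo, hi = param.segment(t, d)
            if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo < 1e-13:
                continue
            res = minimize_scalar(
                lambda s: _evaluate(
                    name, np.clip(param.tensor(t + s * d), 0.0, None)
                ),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if res.fun < best_val - 1e-15:
                best_val = res.fun
                t = t + res.x * d
        t_res, val = run_slsqp(t)
        if val < best_val and param.is_feasible(t_res, tol=1e-9):
            best_val, t = val, t_res
        if best_val > round_start - 1e-12:
            break
    info = {
        "multistart_values": results,
        "multistart_spread": float(np.ptp(results)) if results else 0.0,
        "grad_norm": float(np.linalg.norm(f(t)[1])),
    }
    return float(best_val), t, info


def _conditional_independence_point(param: QParameterization) -> np.ndarray:
    """Parameters of q*(x,y,z) = p(x,z) p(y,z) / p(z), always a member of Q."""
    base = param.base.values
    nx, ny, _ = base.shape
    p_xz = param.base.marginal("XZ")
    p_yz = param.base.marginal("YZ")
    p_z = param.base.marginal("Z")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = p_xz[:, None, :] * p_yz[None, :, :] / p_z[None, None, :]
    q = np.nan_to_num(q, nan=0.0, posinf=0.0)
    return _params_of(param, q)


def _params_of(param: QParameterization, q: np.ndarray) -> np.ndarray:
    """Parameter vector reproducing a tensor q that shares base's marginals."""
    nx, ny, _ = param.base.alphabet_sizes
    diff = q - param.base.values
    return diff[: nx - 1, : ny - 1, :].transpose(2, 0, 1).ravel()


def _repair(param: QParameterization, t: np.ndarray) -> np.ndarray:
    """Pull a near-feasible parameter vector back onto exact marginals.

    Clips negatives and re-runs per-layer proportional fitting until the
    basis reconstruction of the point is feasible to ~1e-13.
    """
    q = np.clip(param.tensor(t), 0.0, None)
    p_xz = param.base.marginal("XZ")
    p_yz = param.base.marginal("YZ")
    for z in range(q.shape[2]):
        m = q[:, :, z]
        for _ in range(500):
            rs = m.sum(axis=1)
            m = m * np.divide(
                p_xz[:, z], rs, out=np.zeros_like(rs), where=rs > 0
            )[:, None]
            cs = m.sum(axis=0)
            m = m * np.divide(
                p_yz[:, z], cs, out=np.zeros_like(cs), where=cs > 0
            )[None, :]
            if (
                np.abs(m.sum(axis=1) - p_xz[:, z]).max() < 1e-14
                and np.abs(m.sum(axis=0) - p_yz[:, z]).max() < 1e-14
            ):
                break
        q[:, :, z] = m
    return _params_of(param, q)


def _zero_unique_candidates(param: QParameterization) -> list[np.ndarray]:
    """Members of Q (if any) where one source is conditionally independent
    of the target given the other.

    min I(Z:X|Y) over Q is exactly zero iff some q in Q factorizes as
    q(x,y,z) = q(x|y) p(y,z); existence is a small linear feasibility
    problem in the conditionals q(x|y).  These vertices are where local
    optimizers struggle most, so exact candidates are worth the two LPs.
    """
    from scipy.optimize import linprog

    out = []
    base = param.base.values
    nx, ny, nz = base.shape
    specs = [
        # (conditional shape, pair marginal to hit, builder)
        ("x|y", param.base.marginal("YZ"), param.base.marginal("XZ")),
        ("y|x", param.base.marginal("XZ"), param.base.marginal("YZ")),
    ]
    for kind, anchor, target in specs:
        na, nb = (nx, ny) if kind == "x|y" else (ny, nx)
        # variables c[a, b] = q(a | b), columns sum to 1
        n_var = na * nb
        a_eq, b_eq = [], []
        for b in range(nb):
            row = np.zeros(n_var)
            row[[a * nb + b for a in range(na)]] = 1.0
            a_eq.append(row)
            b_eq.append(1.0)
        # sum_b c[a, b] * anchor[b, z] = target[a, z]
        for a in range(na):
            for z in range(nz):
                row = np.zeros(n_var)
                for b in range(nb):
                    row[a * nb + b] = anchor[b, z]
                a_eq.append(row)
                b_eq.append(target[a, z])
        res = linprog(
            np.zeros(n_var),
            A_eq=np.array(a_eq),
            b_eq=np.array(b_eq),
            bounds=[(0.0, 1.0)] * n_var,
            method="highs",
        )
        if not res.success:
            continue
        c = res.x.reshape(na, nb)
        if kind == "x|y":
            q = np.einsum("xy,yz->xyz", c, anchor)
        else:
            q = np.einsum("yx,xz->xyz", c, anchor)
        out.append(_repair(param, _params_of(param, q)))
    return out


def _alternating_projection(
    param: QParameterization, max_outer: int = 300, tol: float = 1e-14
) -> np.ndarray:
    """Approach the shared optimum of all four objectives by alternating
    I-projections.

    Every objective differs from -H(Z|X,Y) only by a Q-constant, and
    maximizing H(Z|X,Y) = max over r of sum q log(r(x,y)/q) is biconcave in
    (q, r): the r-step is the XY-marginal of q, the q-step decouples into
    per-z-layer minimum-KL projections of r onto the layer's transportation
    constraints, computed by iterative proportional fitting.  Convergence is
    global but slows near boundary optima, so the result is a warm start,
    not the final answer.
    """
    base = param.base.values
    p_xz = param.base.marginal("XZ")
    p_yz = param.base.marginal("YZ")
    nz = base.shape[2]
    masks = [
        (p_xz[:, z] > 0)[:, None] * (p_yz[:, z] > 0)[None, :] for z in range(nz)
    ]
    q = base.copy()
    prev = np.inf
    for _ in range(max_outer):
        r = q.sum(axis=2)
        for z in range(nz):
            m = r * masks[z]
            if m.sum() <= 0:
                m = np.outer(p_xz[:, z], p_yz[:, z])
            for _ in range(100):
                rs = m.sum(axis=1)
                m *= np.divide(
                    p_xz[:, z], rs, out=np.zeros_like(rs), where=rs > 0
                )[:, None]
                cs = m.sum(axis=0)
                m *= np.divide(
                    p_yz[:, z], cs, out=np.zeros_like(cs), where=cs > 0
                )[None, :]
                if np.abs(rs - p_xz[:, z]).max() < 1e-14:
                    break
            q[:, :, z] = m
        val = _evaluate("i_z_xy", q)
        if prev - val < tol:
            break
        prev = val
    return _repair(param, _params_of(param, q))


@dataclass(frozen=True)
class BrojaSolution:
    """PID components (bits) from the optimization over Q, with diagnostics."""

    ux: float
    uy: float
    r: float
    s: float
    argmin: dict  # objective name -> JointDistribution attaining its optimum
    diagnostics: dict

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.ux, self.uy, self.r, self.s)


def solve(
    dist: JointDistribution,
    *,
    n_starts: int = 5,
    n_polish: int = 40,
    tol: float = 1e-9,
    consistency_tol: float = 1e-6,
    seed: int = 0,
) -> BrojaSolution:
    """Solve the PID of a distribution by four minimizations over its Q set.

    Multistart SLSQP (base point plus seeded random feasible starts) with a
    random-direction line-search polish; the four optima must satisfy the
    decomposition identities UX + R = I(Z:X) and UY + R = I(Z:Y) within
    ``consistency_tol`` or :class:`BrojaConvergenceError` is raised.
    """
    param = parameterize(dist)
    rng = np.random.default_rng(seed)
    n_starts = max(1, n_starts)
    prof = shannon_profile(dist)

    def attempt(extra_starts):
        starts = list(
            sample_q(param, n_starts, seed=int(rng.integers(2**31))).parameters
        )
        starts.append(_conditional_independence_point(param))
        starts.extend(_zero_unique_candidates(param))
        starts.extend(extra_starts)
        optima, argmin_t, diag = {}, {}, {}
        for name in _OBJECTIVES:
            val, t, info = _minimize_one(
                param, name, starts, rng, tol, n_polish
            )
            optima[name] = val
            argmin_t[name] = t
            diag[name] = info
        # The four objectives share their Q-varying part, so each argmin is
        # a strong warm start for the others; a cross-seeded pass lets all
        # four reach the same face before the consistency post-condition.
        cross = list(argmin_t.values())
        for name in _OBJECTIVES:
            val, t, info = _minimize_one(param, name, cross, rng, tol, n_polish)
            if val < optima[name]:
                optima[name] = val
                argmin_t[name] = t
                diag[name] = info
        ux = optima["i_zx_given_y"]
        uy = optima["i_zy_given_x"]
        r = -optima["neg_ci"]
        s = prof.i_z_xy - optima["i_z_xy"]
        resid = max(
            abs(ux + r - prof.i_zx),
            abs(uy + r - prof.i_zy),
            abs(ux + uy + r + s - prof.i_z_xy),
        )
        return {"ux": ux, "uy": uy, "r": r, "s": s}, argmin_t, diag, resid

    best, argmin_t, diag, resid = attempt([_alternating_projection(param)])
    if resid > consistency_tol:
        # escalate: optima at doubly-degenerate vertices (e.g. both unique
        # informations exactly zero) may need the alternating projection run
        # much closer to its fixed point before local refinement can finish
        best, argmin_t, diag, resid = attempt(
            [_alternating_projection(param, max_outer=20000, tol=1e-16)]
        )
    argmin = {
        name: param.distribution(t, tol=1e-8) for name, t in argmin_t.items()
    }
    diag["consistency_residual"] = resid
    if resid > consistency_tol:
        raise BrojaConvergenceError(
            f"optimum inconsistent with the decomposition identities "
            f"(residual {resid:.3e} > {consistency_tol:.0e})",
            best,
        )
    clamped = {}
    for key, val in best.items():
        if val < -_CLAMP:
            raise BrojaConvergenceError(
                f"component {key} = {val:.3e} is significantly negative", best
            )
        clamped[key] = max(val, 0.0)
    diag["clamped"] = {k: best[k] for k in best if best[k] < 0.0}
    return BrojaSolution(
        ux=clamped["ux"], uy=clamped["uy"], r=clamped["r"], s=clamped["s"],
        argmin=argmin, diagnostics=diag,
    )


def objective_profile(
    dist: JointDistribution, q: JointDistribution, *, tol: float = 1e-9
) -> tuple[float, float, float, float]:
    """(I(Z:X|Y), I(Z:Y|X), CI, I(Z:XY)) evaluated at a member q of dist's Q.

    Raises if q does not share the (X,Z) and (Y,Z) marginals of ``dist``.
    """
    for pair in ("XZ", "YZ"):
        err = np.abs(dist.marginal(pair) - q.marginal(pair)).max()
        if err > tol:
            raise ValueError(
                f"q is not in Q: {pair} marginal differs by {err:.3e}"
            )
    return (
        mutual_information(q, "Z", "X", "Y"),
        mutual_information(q, "Z", "Y", "X"),
        shannon_profile(q).co_information,
        mutual_information(q, "Z", "XY"),
    )
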