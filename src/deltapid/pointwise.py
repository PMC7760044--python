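"""Pointwise PID from per-event specificity and ambiguity.

Every positive-probability event (x, y, z) contributes a pointwise mutual
information per source, i(a:z) = i+ - i-, split into the non-negative
specificity i+ = -log2 p(a) and ambiguity i- = -log2 p(a|z).  The pointwise
redundancy takes the per-event minimum of each part across the two sources;
its expectation difference is R, and the remaining components follow from
the decomposition identities.  Components may legitimately be negative
(misinformation): a source whose ambiguity exceeds its specificity on
average misleads about the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distribution import JointDistribution, shannon_profile

__all__ = ["PointwiseTerms", "PpidSolution", "pointwise_terms", "redundancy", "solve"]


@dataclass(frozen=True)
class PointwiseTerms:
    """Per-event pointwise quantities, one row per positive-probability event.

    All arrays are aligned; ``events`` holds (x, y, z) index triples.
    """

    events: np.ndarray        # (n_events, 3) int
    probabilities: np.ndarray  # (n_events,)
    spec_x: np.ndarray         # i+ for source X: -log2 p(x)
    amb_x: np.ndarray          # i- for source X: -log2 p(x|z)
    spec_y: np.ndarray
    amb_y: np.ndarray

    @property
    def pmi_x(self) -> np.ndarray:
        """Pointwise mutual information i(x:z) = i+ - i-."""
        return self.spec_x - self.amb_x

    @property
    def pmi_y(self) -> np.ndarray:
        return self.spec_y - self.amb_y


@dataclass(frozen=True)
class PpidSolution:
    """Pointwise PID components in bits; negatives are misinformation."""

    ux: float
    uy: float
    r: float
    s: float
    rmin_plus: float
    rmin_minus: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.ux, self.uy, self.r, self.s)


def pointwise_terms(dist: JointDistribution) -> PointwiseTerms:
    """Specificity/ambiguity of every positive-probability event.

    Conditionals are exact ratios of tensor sums; zero-probability events
    are excluded (their pointwise terms are undefined and weightless).
    """
    p = dist.values
    p_x = dist.marginal("X")
    p_y = dist.marginal("Y")
    p_z = dist.marginal("Z")
    p_xz = dist.marginal("XZ")
    p_yz = dist.marginal("YZ")
    xs, ys, zs = np.nonzero(p > 0)
    probs = p[xs, ys, zs]
    spec_x = -np.log2(p_x[xs])
    amb_x = -np.log2(p_xz[xs, zs] / p_z[zs])
    spec_y = -np.log2(p_y[ys])
    amb_y = -np.log2(p_yz[ys, zs] / p_z[zs])
    return PointwiseTerms(
        events=np.stack([xs, ys, zs], axis=1),
        probabilities=probs,
        spec_x=spec_x,
        amb_x=amb_x,
        spec_y=spec_y,
        amb_y=amb_y,
    )


def redundancy(dist: JointDistribution) -> tuple[float, float, float]:
    """(rmin+, rmin-, R): expected per-event source-minima of i+ and i-."""
    terms = pointwise_terms(dist)
    w = terms.probabilities
    rmin_plus = float(w @ np.minimum(terms.spec_x, terms.spec_y))
    rmin_minus = float(w @ np.minimum(terms.amb_x, terms.amb_y))
    return rmin_plus, rmin_minus, rmin_plus - rmin_minus


def solve(dist: JointDistribution) -> PpidSolution:
    """Full pointwise PID: R from the specificity/ambiguity minima, the rest
    from UX = I(Z:X) - R, UY = I(Z:Y) - R, S = I(Z:XY) - UX - UY - R."""
    rmin_plus, rmin_minus, r = redundancy(dist)
    prof = shannon_profile(dist)
    ux = prof.i_zx - r
    uy = prof.i_zy - r
    s = prof.i_z_xy - ux - uy - r
    return PpidSolution(
        ux=ux, uy=uy, r=r, s=s, rmin_plus=rmin_plus, rmin_minus=rmin_minus
    )
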