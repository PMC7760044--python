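"""Basic scatter plots of delta space (matplotlib required)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_atlas", "plot_q_cloud"]


def plot_atlas(atlas, component: np.ndarray | None = None, ax=None, **scatter_kw):
    """Scatter the family delta points of an atlas in the (dX, dY) plane.

    ``component`` optionally colors each family (e.g. a PID fraction).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fam = atlas.families
    sc = ax.scatter(
        fam["delta_x"], fam["delta_y"], c=component, s=18, **scatter_kw
    )
    if component is not None:
        ax.figure.colorbar(sc, ax=ax)
    ax.set_xlabel(r"$\delta_X$")
    ax.set_ylabel(r"$\delta_Y$")
    return ax


def plot_q_cloud(sample, ax=None, **scatter_kw):
    """3D scatter of a sampled Q set's delta coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    pts = sample.deltas
    ok = ~np.isnan(pts).any(axis=1)
    ax.scatter(pts[ok, 0], pts[ok, 1], pts[ok, 2], s=8, **scatter_kw)
    ax.set_xlabel(r"$\delta_X$")
    ax.set_ylabel(r"$\delta_Y$")
    ax.set_zlabel(r"$\delta_Z$")
    return ax
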