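"""Optional matplotlib views of fitted results (compute stays elsewhere)."""

from __future__ import annotations

import numpy as np


def plot_manifold(manifold, ax=None, cmap: str = "viridis", levels: int = 30):
    """Contour plot of the landscape phi(y) with cell positions overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(manifold.grid_x, manifold.grid_y, manifold.phi,
                     levels=levels, cmap=cmap)
    ax.scatter(manifold.y[:, 0], manifold.y[:, 1], s=3, c="white", alpha=0.4)
    ax.scatter(manifold.mu[:, 0], manifold.mu[:, 1], s=60, c="red", marker="x")
    ax.figure.colorbar(cs, ax=ax, label=r"$\phi(y) = -\ln \mathcal{P}(y)$")
    ax.set_xlabel("transition coord. 1")
    ax.set_ylabel("transition coord. 2")
    return ax


def plot_streamlines(embedding, arrows, color=None, ax=None, scale: float = 1.0):
    """Quiver plot of projected tensor arrows in a 2-D embedding."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    c = color if color is not None else "steelblue"
    sc = ax.scatter(embedding[:, 0], embedding[:, 1], s=6, c=c, alpha=0.7)
    ax.quiver(embedding[:, 0], embedding[:, 1], arrows[:, 0], arrows[:, 1],
              angles="xy", scale_units="xy",
              scale=1.0 / max(scale, 1e-12), width=0.003, alpha=0.8)
    if color is not None and not isinstance(color, str):
        ax.figure.colorbar(sc, ax=ax)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax
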