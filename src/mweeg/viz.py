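"""Topography plotting for learned spatial patterns."""

from __future__ import annotations

import numpy as np

from .containers import Montage
from .csp import CspModel


def plot_patterns(model: CspModel, montage: Montage, axes=None):
    """Draw each CSP pattern as an interpolated scalp map.

    Patterns show where the largest *change in band-limited variance*
    between the two attentional states projects on the scalp; they are not
    activation maps. Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    k = model.n_components
    if axes is None:
        fig, axes = plt.subplots(1, k, figsize=(2.2 * k, 2.4))
    else:
        fig = axes[0].figure
    pos = montage.positions
    theta = np.linspace(0, 2 * np.pi, 100)
    half = k // 2
    for i, ax in enumerate(np.atleast_1d(axes)):
        vals = model.patterns[:, i]
        lim = np.max(np.abs(vals))
        ax.tricontourf(pos[:, 0], pos[:, 1], vals, levels=12,
                       cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.plot(np.cos(theta), np.sin(theta), color="k", lw=1)
        ax.scatter(pos[:, 0], pos[:, 1], s=6, c="k")
        cls = model.class_order[0] if i < half else model.class_order[1]
        rank = i + 1 if i < half else k - i
        ax.set_title(f"{cls} {rank}", fontsize=9)
        ax.set_aspect("equal")
        ax.axis("off")
    return fig
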