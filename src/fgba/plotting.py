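"""Landscape rendering with the conventional state colours."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .landscape import Landscape

__all__ = ["render_landscape"]

#: forest dark green, grass light, burning red, ash gray
_CMAP = ListedColormap(["#1b5e20", "#f5f0c8", "#d32f2f", "#9e9e9e"])


def render_landscape(landscape: Landscape, path=None, ax=None, title=None):
    """Draw a landscape; save to ``path`` if given, else return the axes."""
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(landscape.cells, cmap=_CMAP, vmin=0, vmax=3,
              interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        if created:
            plt.close(ax.figure)
        return None
    return ax
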