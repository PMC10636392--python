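"""Small deterministic landscapes with hand-verified metric sidecars.

Each fixture returns a landscape together with the exact values of its
geometric observables, counted by hand from the construction — useful as
ground truth for the metric functions and for quick demonstrations.
"""

from __future__ import annotations

import numpy as np

from .landscape import F, G, Landscape

__all__ = ["make_fixture", "FIXTURES"]


def _single_forest_cell_4x4():
    cells = np.full((4, 4), G, dtype=np.uint8)
    cells[1, 1] = F
    # one forest cell: [F]=1/16; its 4 grass neighbours give [FG]=4/16; all
    # grass is one cluster so [FG]cg=[FG]
    return Landscape(cells), {"F": 1 / 16, "G": 15 / 16, "FG": 4 / 16,
                              "FGcg": 4 / 16, "nc": 1}


def _checkerboard_8x8():
    idx = np.indices((8, 8)).sum(axis=0) % 2
    cells = np.where(idx == 0, F, G).astype(np.uint8)
    # 32 singleton grass clusters, each with 4 forest neighbours:
    # [FG] = 32*4/64 = 2; [FG]cg = sum (1/32)*(4/64) / ... = 1/16
    return Landscape(cells), {"F": 0.5, "G": 0.5, "FG": 2.0,
                              "FGcg": 32 * (1 / 64) * (4 / 64) / 0.5,
                              "nc": 32}


def _block_with_hole_10x10():
    ls = Landscape.forest_with_hole(10, None, 0.16)
    # 4x4 grass hole in forest: boundary pair count = 4*4 = 16
    return ls, {"F": 84 / 100, "G": 16 / 100, "FG": 16 / 100,
                "FGcg": 16 / 100, "nc": 1}


def _two_cluster_demo():
    cells = np.full((8, 8), F, dtype=np.uint8)
    cells[1:3, 1:3] = G          # 2x2 hole: 8 boundary pairs
    cells[5, 4:7] = G            # 1x3 hole: 3+2+3 = 8 boundary pairs
    fg = 16 / 64
    fgcg = ((4 / 64) * (8 / 64) + (3 / 64) * (8 / 64)) / (7 / 64)
    return Landscape(cells), {"F": 57 / 64, "G": 7 / 64, "FG": fg,
                              "FGcg": fgcg, "nc": 2}


FIXTURES = {
    "single_forest_cell_4x4": _single_forest_cell_4x4,
    "checkerboard_8x8": _checkerboard_8x8,
    "block_with_hole_10x10": _block_with_hole_10x10,
    "two_cluster_demo": _two_cluster_demo,
}


def make_fixture(name: str, seed=None):
    """Return (landscape, sidecar) for a registered fixture name.

    The sidecar maps observable names ('F', 'G', 'FG', 'FGcg', 'nc') to
    their hand-counted exact values.  ``seed`` is accepted for interface
    uniformity; the registered fixtures are deterministic.
    """
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: "
                         f"{sorted(FIXTURES)}") from None
    return builder()
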