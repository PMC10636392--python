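"""Lattice landscapes and their geometric observables.

The landscape is a periodic square lattice (torus) whose cells each hold one
of four labels: forest (F), grass (G), burning (B) and ash (A).  Adjacency is
4-nearest-neighbour throughout — the same von Neumann neighbourhood used by
every spreading process in the model — so all perimeter and cluster
statistics are consistent with the dynamics that generate them.

Bracketed observables follow the moment-closure convention: ``[x]`` is the
fraction of cells with label x, and ``[xy]`` the number of ordered neighbour
pairs (i, j) with labels (x, y), divided by the number of cells N.  For
distinct labels this counts each unordered x–y adjacency once, so a single
forest cell surrounded by grass has ``[FG] = 4/N``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "F", "G", "B", "A", "LABELS",
    "Landscape", "StateFractions", "ClusterDecomposition",
    "state_fractions", "pair_count", "pair_count_raw",
    "grass_clusters", "weighted_forest_perimeter",
    "read_grid", "write_grid", "read_grid_binary", "write_grid_binary",
]

F, G, B, A = 0, 1, 2, 3
LABELS = "FGBA"
_CHAR_TO_CODE = {c: i for i, c in enumerate(LABELS)}

#: 4-connectivity structuring element (von Neumann neighbourhood).
_VON_NEUMANN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

_MAGIC = b"FGBA"


def _as_code(label) -> int:
    """Accept an int code or a one-character label string."""
    if isinstance(label, str):
        try:
            return _CHAR_TO_CODE[label.upper()]
        except KeyError:
            raise ValueError(f"unknown cell label {label!r}; expected one of 'FGBA'")
    code = int(label)
    if code not in (F, G, B, A):
        raise ValueError(f"unknown cell label code {label!r}")
    return code


@dataclass
class Landscape:
    """A periodic lattice of cell labels.

    Parameters
    ----------
    cells
        2D uint8 array of shape (height, width) with values in {0, 1, 2, 3}
        encoding F, G, B, A.  Stored as-is (no copy).
    """

    cells: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2D array")
        if self.cells.size and self.cells.max() > 3:
            raise ValueError("cell values must be in {0,1,2,3} (F,G,B,A)")

    @property
    def height(self) -> int:
        return self.cells.shape[0]

    @property
    def width(self) -> int:
        return self.cells.shape[1]

    @property
    def N(self) -> int:
        """Total number of cells."""
        return self.cells.size

    def copy(self) -> "Landscape":
        return Landscape(self.cells.copy())

    def counts(self) -> np.ndarray:
        """Cell counts per label, indexed by code [F, G, B, A]."""
        return np.bincount(self.cells.ravel(), minlength=4)

    def vegetation_view(self) -> "Landscape":
        """Ash mapped to grass (A→G); burning cells left untouched."""
        cells = self.cells.copy()
        cells[cells == A] = G
        return Landscape(cells)

    def slow_view(self) -> "Landscape":
        """Slow-timescale view: both B and A mapped to G.

        On the timescale of forest demography, fire converts trees
        effectively straight to grass (grass regrowth on ash is fast
        compared to demography), so balance-equation geometry is computed
        on this two-species view.
        """
        cells = self.cells.copy()
        cells[(cells == B) | (cells == A)] = G
        return Landscape(cells)

    # -- constructors -------------------------------------------------

    @classmethod
    def all_grass(cls, width: int, height: int | None = None) -> "Landscape":
        height = width if height is None else height
        _check_dims(width, height)
        return cls(np.full((height, width), G, dtype=np.uint8))

    @classmethod
    def all_forest(cls, width: int, height: int | None = None) -> "Landscape":
        height = width if height is None else height
        _check_dims(width, height)
        return cls(np.full((height, width), F, dtype=np.uint8))

    @classmethod
    def uniform_random(cls, width: int, height: int | None, forest_fraction: float,
                       seed=None) -> "Landscape":
        """Forest placed i.i.d. with probability ``forest_fraction``, rest grass."""
        height = width if height is None else height
        _check_dims(width, height)
        if not 0.0 <= forest_fraction <= 1.0:
            raise ValueError("forest_fraction must be in [0, 1]")
        rng = np.random.default_rng(seed)
        forest = rng.random((height, width)) < forest_fraction
        cells = np.where(forest, F, G).astype(np.uint8)
        return cls(cells)

    @classmethod
    def forest_with_hole(cls, width: int, height: int | None,
                         hole_fraction: float) -> "Landscape":
        """All-forest landscape with a centred square hole of grass.

        The hole side is rounded to the integer that best matches the
        requested grass fraction.
        """
        height = width if height is None else height
        _check_dims(width, height)
        if not 0.0 <= hole_fraction <= 1.0:
            raise ValueError("hole_fraction must be in [0, 1]")
        n = width * height
        side = int(round(np.sqrt(hole_fraction * n)))
        side = min(side, width, height)
        cells = np.full((height, width), F, dtype=np.uint8)
        r0 = (height - side) // 2
        c0 = (width - side) // 2
        cells[r0:r0 + side, c0:c0 + side] = G
        return cls(cells)

    # -- text round-trip ----------------------------------------------

    def to_text(self) -> str:
        rows = ["".join(LABELS[c] for c in row) for row in self.cells]
        return "\n".join(rows) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Landscape":
        rows = [line for line in text.splitlines() if line.strip()]
        if not rows:
            raise ValueError("empty grid text")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError("ragged grid: rows have differing lengths")
        try:
            cells = np.array([[_CHAR_TO_CODE[c] for c in row] for row in rows],
                             dtype=np.uint8)
        except KeyError as exc:
            raise ValueError(f"unknown cell character {exc.args[0]!r}") from None
        return cls(cells)


def _check_dims(width: int, height: int) -> None:
    if width < 2 or height < 2:
        raise ValueError("lattice dimensions must be >= 2")


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateFractions:
    """Cover fractions [F], [G], [B], [A]; they sum to one."""

    f_F: float
    f_G: float
    f_B: float
    f_A: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_F, self.f_G, self.f_B, self.f_A])


def state_fractions(landscape: Landscape) -> StateFractions:
    """Fraction of cells in each state."""
    counts = landscape.counts()
    frac = counts / landscape.N
    return StateFractions(*frac.tolist())


def _neighbour_shifts(cells: np.ndarray):
    """The four periodic neighbour views (up, down, left, right)."""
    return (np.roll(cells, 1, axis=0), np.roll(cells, -1, axis=0),
            np.roll(cells, 1, axis=1), np.roll(cells, -1, axis=1))


def pair_count_raw(landscape: Landscape, x, y) -> int:
    """Number of ordered neighbour pairs (i, j) with labels (x, y).

    For x != y each unordered x–y adjacency contributes once; for x == y it
    contributes twice (both orderings).
    """
    x, y = _as_code(x), _as_code(y)
    cells = landscape.cells
    total = 0
    for shifted in _neighbour_shifts(cells):
        total += int(np.count_nonzero((cells == x) & (shifted == y)))
    return total


def pair_count(landscape: Landscape, x, y) -> float:
    """Pair density [xy]: ordered neighbour pairs with labels (x, y), per cell."""
    return pair_count_raw(landscape, x, y) / landscape.N


@dataclass
class ClusterDecomposition:
    """Maximal 4-connected grass clusters on the torus.

    Attributes
    ----------
    labels
        2D int array; cluster ids 1..nc on grass cells, 0 elsewhere.
    sizes
        Cell count per cluster (length nc).
    fg_counts
        Forest–grass neighbour-pair count between forest and each cluster: a
        forest cell touching cluster j on two sides contributes 2.
    N
        Total number of lattice cells (normaliser for fraction forms).
    """

    labels: np.ndarray
    sizes: np.ndarray
    fg_counts: np.ndarray
    N: int

    @property
    def nc(self) -> int:
        return len(self.sizes)

    @property
    def g_fractions(self) -> np.ndarray:
        """Per-cluster grass fractions [G]_j = size_j / N."""
        return self.sizes / self.N

    @property
    def fg_fractions(self) -> np.ndarray:
        """Per-cluster interface fractions [FG]_j = pair count / N."""
        return self.fg_counts / self.N

    @property
    def grass_fraction(self) -> float:
        """[G] = sum_j [G]_j."""
        return float(self.sizes.sum()) / self.N

    @property
    def fg_fraction(self) -> float:
        """[FG] = sum_j [FG]_j."""
        return float(self.fg_counts.sum()) / self.N

    def members(self, j: int) -> np.ndarray:
        """Flat cell indices of cluster j (1-based cluster id)."""
        if not 1 <= j <= self.nc:
            raise IndexError(f"cluster index {j} out of range 1..{self.nc}")
        return np.flatnonzero(self.labels.ravel() == j)

    def largest_cluster(self) -> int:
        """Id of the largest cluster; ties broken by lowest id (row-major order)."""
        if self.nc == 0:
            raise ValueError("no grass clusters")
        return int(np.argmax(self.sizes)) + 1


def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected component labelling with periodic boundary conditions."""
    labels, n = ndimage.label(mask, structure=_VON_NEUMANN)
    if n == 0:
        return labels, 0
    # merge components that touch across the wrapped edges (union-find)
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for a, b in ((labels[0, :], labels[-1, :]), (labels[:, 0], labels[:, -1])):
        both = (a > 0) & (b > 0)
        for i, j in zip(a[both], b[both]):
            union(int(i), int(j))

    roots = np.array([find(i) for i in range(n + 1)])
    # compact to 1..nc
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], len(uniq)


def grass_clusters(landscape: Landscape) -> ClusterDecomposition:
    """Decompose the grass phase into maximal 4-connected clusters.

    Burning and ash cells break grass connectivity (they are not grass at
    the instant observed); map them first via :meth:`Landscape.slow_view`
    when the vegetation-only geometry is wanted.
    """
    cells = landscape.cells
    labels, nc = _periodic_label(cells == G)
    if nc == 0:
        empty = np.zeros(0, dtype=np.int64)
        return ClusterDecomposition(labels, empty, empty.astype(float), landscape.N)
    sizes = np.bincount(labels.ravel(), minlength=nc + 1)[1:]
    fg_counts = np.zeros(nc + 1, dtype=np.int64)
    is_forest = cells == F
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbour_labels = np.roll(labels, shift, axis=axis)
        m = is_forest & (neighbour_labels > 0)
        fg_counts += np.bincount(neighbour_labels[m], minlength=nc + 1)
    return ClusterDecomposition(labels, sizes.astype(np.int64), fg_counts[1:], landscape.N)


def weighted_forest_perimeter(decomp: ClusterDecomposition) -> float:
    """Grassland-weighted forest perimeter [FG]_cg.

    The per-cluster interfaces averaged with weights proportional to each
    grass cluster's size: sum_j ([G]_j / [G]) [FG]_j.  It equals the plain
    perimeter [FG] when all grass forms one cluster, and is smaller whenever
    forest fragments the grass phase — fires then reach only part of the
    interface per ignition.  Returns 0 when there is no grass.
    """
    if decomp.nc == 0:
        return 0.0
    g = decomp.g_fractions
    return float(np.sum(g * decomp.fg_fractions) / g.sum())


# ---------------------------------------------------------------------------
# grid file I/O
# ---------------------------------------------------------------------------

def write_grid(path, landscape: Landscape) -> None:
    """Write the plain-text grid format (one row per line, chars FGBA)."""
    with open(path, "w") as fh:
        fh.write(landscape.to_text())


def read_grid(path) -> Landscape:
    with open(path) as fh:
        return Landscape.from_text(fh.read())


def write_grid_binary(path, landscape: Landscape) -> None:
    """Binary grid: magic 'FGBA', uint32 width/height (little endian), raw uint8 codes."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(np.array([landscape.width, landscape.height],
                          dtype="<u4").tobytes())
        fh.write(np.ascontiguousarray(landscape.cells).tobytes())


def read_grid_binary(path) -> Landscape:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != _MAGIC:
        raise ValueError("not a binary FGBA grid file")
    width, height = np.frombuffer(data[4:12], dtype="<u4")
    cells = np.frombuffer(data[12:], dtype=np.uint8)
    if cells.size != width * height:
        raise ValueError("binary grid payload does not match header dimensions")
    return Landscape(cells.reshape(int(height), int(width)).copy())
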