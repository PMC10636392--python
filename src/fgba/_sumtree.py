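"""Flat binary sum tree for O(log N) propensity sampling and updates.

Backed by a plain Python list: the event loop touches a handful of scalar
slots per event, for which list indexing beats NumPy scalar access.
"""

from __future__ import annotations

__all__ = ["SumTree"]


class SumTree:
    """Fixed-capacity tree of nonnegative weights supporting weighted sampling."""

    def __init__(self, n: int):
        size = 1
        while size < n:
            size <<= 1
        self.n = n
        self.size = size
        self.tree = [0.0] * (2 * size)

    @property
    def total(self) -> float:
        return self.tree[1]

    def get(self, i: int) -> float:
        return self.tree[self.size + i]

    def set(self, i: int, value: float) -> None:
        tree = self.tree
        i += self.size
        tree[i] = value
        i >>= 1
        while i:
            tree[i] = tree[2 * i] + tree[2 * i + 1]
            i >>= 1

    def sample(self, r: float) -> int:
        """Index i with cumulative-weight bracket containing r in [0, total)."""
        tree = self.tree
        i = 1
        size = self.size
        # clamp away from the upper edge so float drift cannot push us past
        # the last positive leaf
        if r >= tree[1]:
            r = tree[1] * (1.0 - 1e-12)
        while i < size:
            i <<= 1
            left = tree[i]
            if r >= left:
                r -= left
                i += 1
        return i - size

    def rebuild(self) -> None:
        """Recompute internal nodes from leaves (curbs float drift)."""
        tree = self.tree
        for i in range(self.size - 1, 0, -1):
            tree[i] = tree[2 * i] + tree[2 * i + 1]
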