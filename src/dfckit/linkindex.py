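"""Canonical enumeration of inter-regional links.

An FC matrix over ``N`` regions has ``L = N(N-1)/2`` independent off-diagonal
entries.  Everything downstream (streams, meta-connectivity, module
partitions) addresses links by an integer ordinal, so a single, documented
bijection between ordinals and region pairs is load-bearing: streams and MC
matrices built with different orderings would silently misalign.

The canonical undirected order is row-major over the upper triangle
``(0,1), (0,2), ..., (0,N-1), (1,2), ...`` with 0-based region indices.
A *directed* enumeration over all ``M = N(N-1)`` ordered pairs (diagonal
skipped, row-major) addresses rows of the redundant expanded MC view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LinkIndex"]


@dataclass(frozen=True)
class LinkIndex:
    """Bijections between link ordinals and region pairs for ``N`` regions."""

    n_regions: int
    _rows: np.ndarray = field(init=False, repr=False, compare=False)
    _cols: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError(f"need at least 2 regions, got {self.n_regions}")
        rows, cols = np.triu_indices(self.n_regions, k=1)
        object.__setattr__(self, "_rows", rows)
        object.__setattr__(self, "_cols", cols)

    @property
    def n_links(self) -> int:
        """Number of undirected links L = N(N-1)/2."""
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def n_directed(self) -> int:
        """Number of ordered region pairs M = N(N-1)."""
        return self.n_regions * (self.n_regions - 1)

    # -- undirected enumeration -------------------------------------------

    def pair_of(self, m: int) -> tuple[int, int]:
        """Region pair ``(i, j)``, ``i < j``, of undirected ordinal ``m``."""
        if not 0 <= m < self.n_links:
            raise IndexError(
                f"link ordinal {m} out of range [0, {self.n_links}) for "
                f"N={self.n_regions}"
            )
        return int(self._rows[m]), int(self._cols[m])

    def ordinal_of(self, i: int, j: int) -> int:
        """Undirected ordinal of the link between regions ``i`` and ``j``."""
        n = self.n_regions
        if i == j:
            raise ValueError(f"self-loop ({i},{i}) has no link ordinal")
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"region pair ({i},{j}) out of range for N={n}")
        if i > j:
            i, j = j, i
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    # -- directed enumeration (redundant MC rows) --------------------------

    def directed_pair_of(self, m: int) -> tuple[int, int]:
        """Ordered region pair ``(i, j)``, ``i != j``, of directed ordinal ``m``."""
        n = self.n_regions
        if not 0 <= m < self.n_directed:
            raise IndexError(
                f"directed ordinal {m} out of range [0, {self.n_directed}) "
                f"for N={n}"
            )
        i, r = divmod(m, n - 1)
        j = r if r < i else r + 1
        return i, j

    def directed_ordinal_of(self, i: int, j: int) -> int:
        """Directed ordinal of the ordered pair ``(i, j)``."""
        n = self.n_regions
        if i == j:
            raise ValueError(f"self-loop ({i},{i}) has no directed ordinal")
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"region pair ({i},{j}) out of range for N={n}")
        return i * (n - 1) + (j if j < i else j - 1)

    def directed_to_undirected(self) -> np.ndarray:
        """Length-M array mapping each directed ordinal to its undirected one."""
        n = self.n_regions
        out = np.empty(self.n_directed, dtype=np.int64)
        for m in range(self.n_directed):
            i, j = self.directed_pair_of(m)
            out[m] = self.ordinal_of(i, j)
        return out

    def incident_links(self, i: int) -> np.ndarray:
        """Undirected ordinals of all N-1 links incident on region ``i``."""
        if not 0 <= i < self.n_regions:
            raise IndexError(f"region {i} out of range for N={self.n_regions}")
        mask = (self._rows == i) | (self._cols == i)
        return np.nonzero(mask)[0]
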