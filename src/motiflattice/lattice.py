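"""Periodic FCC lattice in primitive-vector indexing.

Every integer triple ``(i, j, k)`` with ``0 <= i < n1`` etc. is a lattice
site, so a box of dimensions ``(n1, n2, n3)`` has exactly ``V = n1*n2*n3``
sites.  The twelve nearest neighbors of a site are reached by the fixed
offset set ``±(1,0,0), ±(0,1,0), ±(0,0,1), ±(1,-1,0), ±(0,1,-1), ±(1,0,-1)``
(periodic wrap).  Mapping to Cartesian space uses the primitive vectors

    a1 = (1,1,0)/sqrt(2),  a2 = (0,1,1)/sqrt(2),  a3 = (1,0,1)/sqrt(2),

which give nearest-neighbor distance 1 (one monomer length).
"""

from __future__ import annotations

import numpy as np

#: coordination number of the FCC lattice
Z = 12

#: the 12 neighbor offsets in primitive-vector coordinates
NEIGHBOR_OFFSETS = np.array(
    [
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
        (1, -1, 0), (-1, 1, 0),
        (0, 1, -1), (0, -1, 1),
        (1, 0, -1), (-1, 0, 1),
    ],
    dtype=np.int64,
)

#: primitive lattice vectors as rows (Cartesian, nearest-neighbor distance 1)
PRIMITIVE_VECTORS = np.array(
    [[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 1.0]]
) / np.sqrt(2.0)


class FccLattice:
    """Periodic FCC lattice with a precomputed neighbor table.

    Parameters
    ----------
    dims
        Box dimensions ``(n1, n2, n3)`` in primitive-vector indexing.
        Every dimension must be at least 3, otherwise the periodic wrap
        would map two distinct offsets onto the same neighbor.
    """

    def __init__(self, dims):
        dims = tuple(int(d) for d in dims)
        if len(dims) != 3:
            raise ValueError("dims must be a triple (n1, n2, n3)")
        if any(d < 3 for d in dims):
            raise ValueError(
                f"every lattice dimension must be >= 3 (got {dims}); smaller "
                "boxes would duplicate neighbors under periodic wrap"
            )
        self.dims = dims
        self.V = dims[0] * dims[1] * dims[2]
        self.neighbor_table = self._build_neighbor_table()

    def _build_neighbor_table(self) -> np.ndarray:
        n1, n2, n3 = self.dims
        i, j, k = np.meshgrid(
            np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"
        )
        coords = np.stack(
            [i.ravel(), j.ravel(), k.ravel()], axis=1
        )  # (V, 3)
        table = np.empty((self.V, Z), dtype=np.int32)
        for m, off in enumerate(NEIGHBOR_OFFSETS):
            nb = (coords + off) % np.array(self.dims)
            table[:, m] = self.ravel(nb[:, 0], nb[:, 1], nb[:, 2])
        return table

    # -- index conversions -------------------------------------------------

    def ravel(self, i, j, k):
        """Flat site index of primitive coordinates ``(i, j, k)``."""
        n1, n2, n3 = self.dims
        return (np.asarray(i) % n1) * (n2 * n3) + (np.asarray(j) % n2) * n3 + (
            np.asarray(k) % n3
        )

    def unravel(self, site):
        n1, n2, n3 = self.dims
        site = np.asarray(site)
        return np.stack(
            [site // (n2 * n3), (site // n3) % n2, site % n3], axis=-1
        )

    # -- queries -----------------------------------------------------------

    def neighbors(self, site: int) -> np.ndarray:
        """The 12 sites adjacent to ``site`` (periodic wrap)."""
        if not 0 <= site < self.V:
            raise IndexError(f"site {site} outside lattice of {self.V} sites")
        return self.neighbor_table[site].copy()

    def are_adjacent(self, s1: int, s2: int) -> bool:
        return s2 in self.neighbor_table[s1]

    def common_neighbors(self, s1: int, s2: int) -> np.ndarray:
        """Sites adjacent to both ``s1`` and ``s2``."""
        return np.intersect1d(self.neighbor_table[s1], self.neighbor_table[s2])

    def cartesian(self, coords) -> np.ndarray:
        """Map primitive integer coordinates to Cartesian positions."""
        return np.asarray(coords, dtype=float) @ PRIMITIVE_VECTORS

    def __repr__(self):  # pragma: no cover
        return f"FccLattice(dims={self.dims}, V={self.V})"
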