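"""Patch graphs and the density-independent dispersal operator.

A :class:`Topology` is the undirected graph of accessible habitat patches.
For a migration rate ``D`` the implied dispersal matrix has
``M[j, j] = 1 - D`` and ``M[i, j] = D / n_j`` for each neighbor ``i`` of
``j``, where ``n_j`` is the connectivity of patch ``j`` — a migrant leaves
with probability ``D`` and picks a destination uniformly among the
neighbors. Columns sum to one, so dispersal conserves total density.

Defect sites ("inaccessible" patches in a lattice) are modeled as absent
nodes: they appear in no neighbor list and the connectivity of their
neighbors is reduced accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = ["Topology", "build_topology", "dispersal_matrix", "two_coloring"]

KINDS = ("two_patch", "chain_1d", "lattice_2d", "equal_coupling")


@dataclass(frozen=True)
class Topology:
    """Immutable patch graph.

    ``adjacency[i]`` lists the accessible neighbors of accessible patch
    ``i`` (0-based, re-indexed after defect removal). ``site_labels[i]``
    is the patch's label in the full (pre-defect) geometry: an integer for
    chains, a (row, col) pair for 2-D lattices.
    """

    kind: str
    L: int
    adjacency: tuple[tuple[int, ...], ...]
    dims: Optional[tuple[int, ...]] = None
    boundary: str = "periodic"
    defect_mask: frozenset = field(default_factory=frozenset)
    site_labels: tuple = ()

    @property
    def connectivity(self) -> np.ndarray:
        """Per-patch neighbor count ``n_i``."""
        return np.array([len(nb) for nb in self.adjacency], dtype=int)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.L))
        for i, nbrs in enumerate(self.adjacency):
            g.add_edges_from((i, j) for j in nbrs)
        return g


def _dedupe(neighbors: Iterable[int], self_idx: int) -> tuple[int, ...]:
    seen = []
    for j in neighbors:
        if j != self_idx and j not in seen:
            seen.append(j)
    return tuple(seen)


def build_topology(
    kind: str,
    dims=None,
    boundary: str = "periodic",
    defect_mask: Sequence = (),
) -> Topology:
    """Construct a patch graph.

    Parameters
    ----------
    kind : {"two_patch", "chain_1d", "lattice_2d", "equal_coupling"}
    dims : int or (rows, cols)
        Number of patches (chain_1d / equal_coupling) or lattice shape
        (lattice_2d). Ignored for two_patch.
    boundary : {"periodic", "open"}
        Chain and lattice boundary condition. A periodic 2-patch chain and
        the two_patch kind coincide (duplicate edges are merged so each
        patch has one distinct neighbor).
    defect_mask : sequence
        Inaccessible sites: flat indices for chains, (row, col) pairs for
        lattices. Removed from the graph entirely.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown topology kind {kind!r}; expected one of {KINDS}")
    if boundary not in ("periodic", "open"):
        raise ValueError("boundary must be 'periodic' or 'open'")

    if kind == "two_patch":
        labels = [0, 1]
        adjacency = {0: (1,), 1: (0,)}
        defects = frozenset()
        dims_out: Optional[tuple[int, ...]] = (2,)
    elif kind == "chain_1d":
        n = int(dims)
        if n < 1:
            raise ValueError("chain_1d needs at least one patch")
        defects = frozenset(int(d) for d in defect_mask)
        if any(d < 0 or d >= n for d in defects):
            raise ValueError("defect site out of bounds")
        labels = [i for i in range(n) if i not in defects]
        adjacency = {}
        for i in labels:
            if boundary == "periodic":
                nbrs = [(i - 1) % n, (i + 1) % n]
            else:
                nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
            adjacency[i] = _dedupe((j for j in nbrs if j not in defects), i)
        dims_out = (n,)
    elif kind == "lattice_2d":
        rows, cols = (int(dims[0]), int(dims[1]))
        if rows < 1 or cols < 1:
            raise ValueError("lattice_2d needs positive dimensions")
        defects = frozenset((int(r), int(c)) for r, c in defect_mask)
        if any(not (0 <= r < rows and 0 <= c < cols) for r, c in defects):
            raise ValueError("defect site out of bounds")
        labels = [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in defects]
        adjacency = {}
        for r, c in labels:
            if boundary == "periodic":
                nbrs = [((r - 1) % rows, c), ((r + 1) % rows, c), (r, (c - 1) % cols), (r, (c + 1) % cols)]
            else:
                nbrs = [(rr, cc) for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                        if 0 <= rr < rows and 0 <= cc < cols]
            adjacency[(r, c)] = _dedupe((p for p in nbrs if p not in defects), (r, c))
        dims_out = (rows, cols)
    else:  # equal_coupling
        n = int(dims)
        if n < 1:
            raise ValueError("equal_coupling needs at least one patch")
        defects = frozenset(int(d) for d in defect_mask)
        labels = [i for i in range(n) if i not in defects]
        adjacency = {i: tuple(j for j in labels if j != i) for i in labels}
        dims_out = (n,)

    if not labels:
        raise ValueError("defect mask removed every patch; no accessible site left")

    index = {lab: i for i, lab in enumerate(labels)}
    adj = tuple(tuple(index[j] for j in adjacency[lab]) for lab in labels)
    topo = Topology(
        kind=kind,
        L=len(labels),
        adjacency=adj,
        dims=dims_out,
        boundary=boundary,
        defect_mask=frozenset(defects),
        site_labels=tuple(labels),
    )
    if topo.L > 1 and not nx.is_connected(topo.graph()):
        warnings.warn("topology is disconnected (defects split the graph); simulation is still legal",
                      stacklevel=2)
    return topo


def dispersal_matrix(topology: Topology, D: float) -> np.ndarray:
    """Column-stochastic dispersal matrix ``M(D)``.

    ``M[j, j] = 1 - D`` and ``M[i, j] = D / n_j`` on edges. Diagonal entries
    are filled as ``1 - n_j * (D / n_j)`` so each column sums to exactly 1
    in floating point. Isolated patches (``n_j = 0``) keep all residents.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("migration rate D must lie in [0, 1]")
    L = topology.L
    M = np.zeros((L, L))
    for j, nbrs in enumerate(topology.adjacency):
        k = len(nbrs)
        if k == 0:
            M[j, j] = 1.0
            continue
        off = D / k
        for i in nbrs:
            M[i, j] = off
        M[j, j] = 1.0 - off * k
    return M


def two_coloring(topology: Topology) -> Optional[np.ndarray]:
    """Proper 2-coloring of the patch graph, or None if not bipartite.

    Returns an int array of 0/1 colors; adjacent patches always receive
    opposite colors. Needed by the checkerboard order parameter and the
    UDUD attractor classifier.
    """
    g = topology.graph()
    if not nx.is_bipartite(g):
        return None
    colors = np.zeros(topology.L, dtype=int)
    for component in nx.connected_components(g):
        coloring = nx.algorithms.bipartite.color(g.subgraph(component))
        for node, col in coloring.items():
            colors[node] = col
    return colors
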