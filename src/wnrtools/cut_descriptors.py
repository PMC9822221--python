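"""Theta*-classes (Djokovic–Winkler cut method) and distance descriptors.

Two edges ``p = r1 s1`` and ``q = r2 s2`` are Theta-related when

    d(r1, r2) + d(s1, s2)  !=  d(r1, s2) + d(s1, r2).

On partial cubes (which all benzenoid-type skeletons are) Theta is an
equivalence; its classes ``B_1 .. B_k`` are exactly the "elementary cuts":
removing one class splits the graph into two convex components with vertex
counts ``n1, n2`` and edge counts ``m1, m2``.  The eleven distance-based
descriptors are bilinear assemblies of these per-class parameters:

===============  ======================================================
Vertex Wiener    W    = sum n1 n2
Edge Wiener      We   = sum m1 m2
Mixed Wiener     Wev  = 1/2 sum (n1 m2 + n2 m1)
Vertex Szeged    Szv  = sum |B| n1 n2
Edge Szeged      Sze  = sum |B| m1 m2
Mixed Szeged     Szev = 1/2 sum |B| (n1 m2 + n2 m1)
Padmakar–Ivan    PI   = |E|^2 - sum |B|^2
Schultz          S    = 2 sum (n1 m2 + n2 m1) + |E| |V|
Gutman           Gut  = sum (4 m1 m2 - |B|^2) + 2 |E|^2
Vertex Mostar    Mov  = sum |B| |n1 - n2|
Edge Mostar      Moe  = sum |B| |m1 - m2|
===============  ======================================================

The engine certifies the partial-cube property en route (every class must
leave exactly two components) and refuses other graphs rather than
returning silently wrong cut-method values.  All accumulation is in exact
integer arithmetic; the half-integer factors of Wev/Szev are checked for
evenness before halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from wnrtools.ribbon_graphs import MolecularGraph

__all__ = [
    "DESCRIPTOR_NAMES",
    "NotPartialCubeError",
    "ThetaClass",
    "all_pairs_distances",
    "theta_classes",
    "distance_indices",
    "indices_from_classes",
    "wiener_oracle",
    "schultz_oracle",
    "gutman_oracle",
    "theta_class_table",
]

DESCRIPTOR_NAMES = (
    "W", "We", "Wev", "Szv", "Sze", "Szev", "PI", "S", "Gut", "Mov", "Moe",
)


class NotPartialCubeError(ValueError):
    """The Theta* classes of the input do not behave like elementary cuts."""


@dataclass(frozen=True)
class ThetaClass:
    """One Theta*-class with its two-component split parameters.

    ``n1 + n2 = |V|`` and ``m1 + m2 = |E| - |B|``; the component containing
    vertex 0 is component 1 by convention.
    """

    edges: tuple[tuple[int, int], ...]
    n1: int
    n2: int
    m1: int
    m2: int

    @property
    def size(self) -> int:
        return len(self.edges)


def all_pairs_distances(mg: MolecularGraph) -> np.ndarray:
    """Exact BFS shortest-path distance matrix, int16.

    Raises ``ValueError`` naming the components if the graph is
    disconnected.
    """
    n = mg.n_vertices
    edges = mg.edge_array()
    adj = sp.csr_matrix(
        (np.ones(len(edges), dtype=np.int8),
         (edges[:, 0], edges[:, 1])),
        shape=(n, n),
    )
    adj = adj + adj.T
    ncomp, labels = csgraph.connected_components(adj, directed=False)
    if ncomp != 1:
        comps = [np.flatnonzero(labels == i).tolist() for i in range(ncomp)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    dist = csgraph.shortest_path(adj, method="D", unweighted=True)
    return dist.astype(np.int16)


def _union_find_classes(edges: np.ndarray, dist: np.ndarray) -> list[list[int]]:
    """Partition edge indices by the transitive closure of Theta."""
    m = len(edges)
    parent = np.arange(m)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    r = edges[:, 0]
    s = edges[:, 1]
    di = dist.astype(np.int32)
    for i in range(m):
        ri, si = edges[i]
        lhs = di[ri, r] + di[si, s]
        rhs = di[ri, s] + di[si, r]
        related = np.flatnonzero(lhs != rhs)
        for j in related:
            if j <= i:
                continue
            ra, rb = find(i), find(int(j))
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    # deterministic order: by smallest contained edge (endpoint pair)
    return sorted(groups.values(), key=lambda idx: tuple(edges[idx[0]]))


def theta_classes(
    mg: MolecularGraph, dist: np.ndarray | None = None
) -> list[ThetaClass]:
    """Theta*-classes of a partial cube with their cut parameters.

    The pairwise relation is closed transitively (a no-op on genuine
    partial cubes, where Theta is already transitive).  Each class is
    certified by deletion: if the graph does not fall into exactly two
    components a :class:`NotPartialCubeError` is raised.
    """
    if dist is None:
        dist = all_pairs_distances(mg)
    n = mg.n_vertices
    edges = mg.edge_array()
    m = len(edges)
    groups = _union_find_classes(edges, dist)

    out: list[ThetaClass] = []
    keep = np.ones(m, dtype=bool)
    for idx in groups:
        keep[:] = True
        keep[idx] = False
        kept = edges[keep]
        adj = sp.csr_matrix(
            (np.ones(len(kept), dtype=np.int8), (kept[:, 0], kept[:, 1])),
            shape=(n, n),
        )
        ncomp, labels = csgraph.connected_components(adj + adj.T, directed=False)
        if ncomp != 2:
            raise NotPartialCubeError(
                f"deleting the Theta*-class of edge {tuple(edges[idx[0]])} "
                f"left {ncomp} components (expected 2); the input is not a "
                "partial cube"
            )
        side1 = labels == labels[0]
        n1 = int(side1.sum())
        n2 = n - n1
        both1 = side1[kept[:, 0]] & side1[kept[:, 1]]
        m1 = int(both1.sum())
        m2 = len(kept) - m1
        out.append(
            ThetaClass(
                edges=tuple(tuple(int(x) for x in edges[i]) for i in idx),
                n1=n1, n2=n2, m1=m1, m2=m2,
            )
        )
    assert sum(tc.size for tc in out) == m
    return out


def indices_from_classes(
    classes: list[ThetaClass], n_vertices: int, n_edges: int
) -> dict[str, int]:
    """Assemble the eleven descriptors from Theta*-class parameters."""
    E, N = n_edges, n_vertices
    W = We = WevX2 = Szv = Sze = SzevX2 = 0
    sumB2 = 0
    mixed = 0  # sum (n1 m2 + n2 m1)
    Mov = Moe = 0
    fourm1m2 = 0
    for tc in classes:
        B, n1, n2, m1, m2 = tc.size, tc.n1, tc.n2, tc.m1, tc.m2
        W += n1 * n2
        We += m1 * m2
        cross = n1 * m2 + n2 * m1
        WevX2 += cross
        Szv += B * n1 * n2
        Sze += B * m1 * m2
        SzevX2 += B * cross
        sumB2 += B * B
        mixed += cross
        fourm1m2 += 4 * m1 * m2 - B * B
        Mov += B * abs(n1 - n2)
        Moe += B * abs(m1 - m2)
    if WevX2 % 2 or SzevX2 % 2:
        raise ArithmeticError(
            "Wev/Szev half-sums are odd; integrality of the mixed Wiener/"
            "Szeged descriptors is violated for this input"
        )
    return {
        "W": W,
        "We": We,
        "Wev": WevX2 // 2,
        "Szv": Szv,
        "Sze": Sze,
        "Szev": SzevX2 // 2,
        "PI": E * E - sumB2,
        "S": 2 * mixed + E * N,
        "Gut": fourm1m2 + 2 * E * E,
        "Mov": Mov,
        "Moe": Moe,
    }


def distance_indices(
    mg: MolecularGraph, dist: np.ndarray | None = None
) -> dict[str, int]:
    """All eleven distance-based descriptors via the cut method."""
    if dist is None:
        dist = all_pairs_distances(mg)
    classes = theta_classes(mg, dist)
    return indices_from_classes(classes, mg.n_vertices, mg.n_edges)


# ----------------------------------------------------------------------
# independent direct-summation oracles
# ----------------------------------------------------------------------

def wiener_oracle(dist: np.ndarray) -> int:
    """W = sum over unordered pairs of d(u, v), straight from the matrix."""
    return int(np.sum(dist, dtype=np.int64)) // 2


def schultz_oracle(mg: MolecularGraph, dist: np.ndarray) -> int:
    """S = sum over unordered pairs of (deg u + deg v) d(u, v)."""
    deg = mg.degrees()
    total = deg[:, None] + deg[None, :]
    return int(np.sum(total * dist.astype(np.int64), dtype=np.int64)) // 2


def gutman_oracle(mg: MolecularGraph, dist: np.ndarray) -> int:
    """Gut = sum over unordered pairs of (deg u * deg v) d(u, v)."""
    deg = mg.degrees()
    total = deg[:, None] * deg[None, :]
    return int(np.sum(total * dist.astype(np.int64), dtype=np.int64)) // 2


def theta_class_table(classes: list[ThetaClass]) -> list[dict]:
    """Rows (class id, |B|, n1, n2, m1, m2) for CSV/JSON export."""
    return [
        {
            "class": i,
            "size": tc.size,
            "n1": tc.n1,
            "n2": tc.n2,
            "m1": tc.m1,
            "m2": tc.m2,
            "min_edge": f"{tc.edges[0][0]}-{tc.edges[0][1]}",
        }
        for i, tc in enumerate(classes)
    ]
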