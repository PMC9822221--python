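"""Construction of parallelogram benzenoids, ZNR units and WNR chains.

Geometry
--------
Graphs are embedded on the honeycomb lattice using exact integer
coordinates ``(x, y)``: the Cartesian position of a carbon is
``(sqrt(3)/2 * x * L, y/2 * L)`` with ``L`` the C–C bond length, so every
lattice edge has the integer displacement ``(0, ±2)`` or ``(±1, ±1)``.
Hexagon centres sit at ``(2b + a, 3a)`` for integers ``a, b``; a lattice
point is a carbon site iff ``x + y`` is even and ``y % 3 != 0``.

The r-by-c parallelogram benzenoid ``M(r, c)`` consists of the hexagons
``(i, j) -> centre (2j + i, 3i)`` for ``0 <= i < r`` rows and
``0 <= j < c`` columns; rows are offset by half a hexagon, producing two
zigzag sides of r teeth and two of c teeth.

The zigzag-edged nanographene unit ZNR(r,c) couples ``M(r, c)`` to its
glide-reflection image through r parallel single bonds attached at the
right-hand zigzag teeth ``R_i = (2c - 1 + i, 3i - 1)``; the wave-like
ribbon WNR(r,c,n) is the orbit of the parallelogram under k = 0..2n-1
applications of the glide map

    f(x, y) = ((x - y)/2 + 2c + r,  -(3x + y)/2 + 3r - 6),

with the bridge bonds carried along by f.  Successive parallelograms
alternate between the two mirror-image slants, which produces the wave.
This junction is pinned structurally: it reproduces the known bond-degree
partition and the distance-descriptor values of the ribbon family (see
``docs/methods.md`` for how the junction was certified).

Vertices are numbered 0..N-1 in lexicographic order of their lattice
coordinates, so all outputs are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "RibbonSpec",
    "MolecularGraph",
    "build_parallelogram",
    "build_znr",
    "build_wnr",
    "export_graph",
    "read_graph",
    "BOND_LENGTH_ANGSTROM",
]

#: C–C bond length used when exporting Cartesian coordinates (XYZ/SDF).
BOND_LENGTH_ANGSTROM = 1.42

# corner offsets of a pointy-top hexagon, in ring order
_CORNERS = ((1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1))


class ParameterError(ValueError):
    """Raised for invalid ribbon parameters."""


@dataclass(frozen=True)
class RibbonSpec:
    """Parameter triple of a wavy zigzag nanoribbon WNR(r, c, n).

    Parameters
    ----------
    r : int
        Rows of hexagons of each composing parallelogram (>= 1).  Also the
        number of coupling bonds at every junction.
    c : int
        Columns of hexagons of each composing parallelogram (>= 1).
    n : int
        Number of chained ZNR(r, c) units (>= 1); the ribbon contains
        2n parallelograms.
    """

    r: int
    c: int
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("r", "c", "n"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def num_vertices(self) -> int:
        """Carbon count 4n(cr + c + r)."""
        r, c, n = self.r, self.c, self.n
        return 4 * n * (c * r + c + r)

    @property
    def num_edges(self) -> int:
        """Bond count n(2c(3r+2) + 5r - 2) + r(n - 1)."""
        r, c, n = self.r, self.c, self.n
        return n * (2 * c * (3 * r + 2) + 5 * r - 2) + r * (n - 1)


class MolecularGraph:
    """Hydrogen-suppressed carbon skeleton with an integer lattice embedding.

    Vertices are 0..N-1; ``coords[i]`` is the integer honeycomb coordinate
    of vertex i (may be absent for externally supplied graphs).
    """

    def __init__(
        self,
        edges,
        coords: np.ndarray | None = None,
        provenance: str = "external",
    ) -> None:
        g = nx.Graph()
        g.add_edges_from((int(u), int(v)) for u, v in edges)
        if nx.number_of_selfloops(g):
            raise ValueError("molecular graph must be simple (no self-loops)")
        n = g.number_of_nodes()
        if sorted(g.nodes()) != list(range(n)):
            raise ValueError("vertex identifiers must be 0..N-1 without gaps")
        self._graph = g
        self.coords = None if coords is None else np.asarray(coords, dtype=np.int64)
        if self.coords is not None and len(self.coords) != n:
            raise ValueError("coords must have one row per vertex")
        self.provenance = provenance

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_vertices(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted (m, 2) integer array with u < v per row."""
        e = np.array(sorted(tuple(sorted(t)) for t in self._graph.edges()), dtype=np.int64)
        return e.reshape(-1, 2)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_vertices, dtype=np.int64)
        for v, deg in self._graph.degree():
            d[v] = deg
        return d

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self._graph, nodelist=range(self.n_vertices))

    def is_connected(self) -> bool:
        return nx.is_connected(self._graph)

    def validate_skeleton(self) -> None:
        """Assert the structural invariants of a built nanoribbon skeleton:
        connected, bipartite, degrees in {2, 3}."""
        if not nx.is_connected(self._graph):
            raise ValueError("skeleton must be connected")
        if not nx.is_bipartite(self._graph):
            raise ValueError("skeleton must be bipartite")
        degs = set(dict(self._graph.degree()).values())
        if not degs <= {2, 3}:
            raise ValueError(f"carbon degrees must be 2 or 3, found {sorted(degs)}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MolecularGraph({self.provenance}: {self.n_vertices} vertices, "
            f"{self.n_edges} edges)"
        )


# ----------------------------------------------------------------------
# lattice helpers
# ----------------------------------------------------------------------

def _parallelogram_points(r: int, c: int):
    """Vertex set and edge set (as coordinate pairs) of M(r, c)."""
    vertices: set[tuple[int, int]] = set()
    edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for i in range(r):
        for j in range(c):
            cx, cy = 2 * j + i, 3 * i
            pts = [(cx + dx, cy + dy) for dx, dy in _CORNERS]
            vertices.update(pts)
            for k in range(6):
                a, b = pts[k], pts[(k + 1) % 6]
                edges.add((min(a, b), max(a, b)))
    return vertices, edges


def _glide(p: tuple[int, int], r: int, c: int) -> tuple[int, int]:
    """Glide-reflection advancing the chain by one parallelogram."""
    x, y = p
    return ((x - y) // 2 + 2 * c + r, -(3 * x + y) // 2 + 3 * r - 6)


def _finalize(vertices, edges, provenance: str) -> MolecularGraph:
    order = sorted(vertices)
    index = {p: i for i, p in enumerate(order)}
    g = MolecularGraph(
        ((index[a], index[b]) for a, b in edges),
        coords=np.array(order, dtype=np.int64),
        provenance=provenance,
    )
    return g


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------

def build_parallelogram(r: int, c: int) -> MolecularGraph:
    """Build the r-by-c parallelogram benzenoid M(r, c).

    The result has 2(rc + r + c) carbons and 3rc + 2r + 2c - 1 bonds.
    """
    spec = RibbonSpec(r, c, 1)  # validates r, c
    vertices, edges = _parallelogram_points(spec.r, spec.c)
    mg = _finalize(vertices, edges, f"parallelogram({r},{c})")
    assert mg.n_vertices == 2 * (r * c + r + c)
    assert mg.n_edges == 3 * r * c + 2 * r + 2 * c - 1
    return mg


def build_wnr(spec: RibbonSpec | None = None, r: int | None = None,
              c: int | None = None, n: int | None = None) -> MolecularGraph:
    """Build the wave-like nanoribbon WNR(r, c, n).

    Accepts either a :class:`RibbonSpec` or keyword parameters r, c, n.
    The graph is the glide orbit of the base parallelogram: parallelogram
    k is f^k(M(r, c)) and consecutive parallelograms are joined by the r
    coupling bonds f^k({R_i -> R_i + (1, -1)}).
    """
    if spec is None:
        spec = RibbonSpec(int(r), int(c), 1 if n is None else int(n))
    r, c, n = spec.r, spec.c, spec.n

    base_v, base_e = _parallelogram_points(r, c)
    base_bridges = [
        ((2 * c - 1 + i, 3 * i - 1), (2 * c + i, 3 * i - 2)) for i in range(r)
    ]

    vertices: set[tuple[int, int]] = set()
    edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    cur_v, cur_e, cur_b = base_v, base_e, base_bridges
    for k in range(2 * n):
        if vertices & cur_v:
            raise AssertionError("internal error: parallelogram overlap")
        vertices |= cur_v
        edges |= cur_e
        if k < 2 * n - 1:
            for a, b in cur_b:
                edges.add((min(a, b), max(a, b)))
        if k < 2 * n - 1:
            cur_v = {_glide(p, r, c) for p in cur_v}
            cur_e = {
                (min(_glide(a, r, c), _glide(b, r, c)),
                 max(_glide(a, r, c), _glide(b, r, c)))
                for a, b in cur_e
            }
            cur_b = [(_glide(a, r, c), _glide(b, r, c)) for a, b in cur_b]

    mg = _finalize(vertices, edges, f"WNR({r},{c},{n})")
    if mg.n_vertices != spec.num_vertices or mg.n_edges != spec.num_edges:
        raise AssertionError(
            "constructed ribbon does not match the closed-form vertex/edge "
            f"counts: got ({mg.n_vertices}, {mg.n_edges}), expected "
            f"({spec.num_vertices}, {spec.num_edges})"
        )
    mg.validate_skeleton()
    return mg


def build_znr(r: int, c: int) -> MolecularGraph:
    """Build the zigzag-edged nanographene unit ZNR(r, c) = WNR(r, c, 1)."""
    mg = build_wnr(RibbonSpec(r, c, 1))
    mg.provenance = f"ZNR({r},{c})"
    return mg


# ----------------------------------------------------------------------
# io
# ----------------------------------------------------------------------

def cartesian_coords(mg: MolecularGraph) -> np.ndarray:
    """Cartesian (x, y) positions in Angstrom for the lattice embedding."""
    if mg.coords is None:
        raise ValueError("graph has no lattice embedding")
    scale = BOND_LENGTH_ANGSTROM / 2.0
    xy = np.empty((mg.n_vertices, 2), dtype=float)
    xy[:, 0] = mg.coords[:, 0] * math.sqrt(3.0) * scale
    xy[:, 1] = mg.coords[:, 1] * scale
    return xy


def _write_edgelist(mg: MolecularGraph, fh) -> None:
    for u, v in mg.edge_array():
        fh.write(f"{u}\t{v}\n")


def _write_xyz(mg: MolecularGraph, fh) -> None:
    xy = cartesian_coords(mg)
    fh.write(f"{mg.n_vertices}\n{mg.provenance}\n")
    for x, y in xy:
        fh.write(f"C {x:.6f} {y:.6f} 0.000000\n")


def _write_sdf(mg: MolecularGraph, fh) -> None:
    try:
        from rdkit import Chem
        from rdkit.Geometry import Point3D
    except ImportError as exc:  # pragma: no cover - rdkit present in CI env
        raise RuntimeError("SDF export requires rdkit") from exc
    xy = cartesian_coords(mg)
    mol = Chem.RWMol()
    for _ in range(mg.n_vertices):
        mol.AddAtom(Chem.Atom(6))
    for u, v in mg.edge_array():
        mol.AddBond(int(u), int(v), Chem.BondType.SINGLE)
    conf = Chem.Conformer(mg.n_vertices)
    for i, (x, y) in enumerate(xy):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), 0.0))
    m = mol.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mg.provenance)
    fh.write(Chem.MolToMolBlock(m, kekulize=False))
    fh.write("$$$$\n")


def export_graph(mg: MolecularGraph, path, fmt: str | None = None) -> None:
    """Write a graph as 'edgelist', 'graphml', 'xyz' or 'sdf'.

    ``fmt`` defaults to the file suffix.  Edge lists are two-column,
    tab-separated, 0-based.  XYZ/SDF use the planar lattice embedding
    scaled to a 1.42 Angstrom bond length (carbons only, implicit H).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("edgelist", "txt", "tsv"):
        with open(path, "w") as fh:
            _write_edgelist(mg, fh)
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(range(mg.n_vertices))
        g.add_edges_from(map(tuple, mg.edge_array()))
        if mg.coords is not None:
            for i in range(mg.n_vertices):
                g.nodes[i]["x"] = int(mg.coords[i, 0])
                g.nodes[i]["y"] = int(mg.coords[i, 1])
        nx.write_graphml(g, path)
    elif fmt == "xyz":
        with open(path, "w") as fh:
            _write_xyz(mg, fh)
    elif fmt == "sdf":
        with open(path, "w") as fh:
            _write_sdf(mg, fh)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def read_graph(path, fmt: str | None = None) -> MolecularGraph:
    """Read an edge list or GraphML file as a :class:`MolecularGraph`."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        relabel = {v: int(v) for v in g.nodes()}
        g = nx.relabel_nodes(g, relabel)
        coords = None
        if all("x" in g.nodes[v] and "y" in g.nodes[v] for v in g.nodes()):
            coords = np.array(
                [[int(g.nodes[i]["x"]), int(g.nodes[i]["y"])] for i in sorted(g.nodes())]
            )
        return MolecularGraph(g.edges(), coords=coords, provenance=str(path.name))
    if fmt in ("edgelist", "txt", "tsv"):
        edges = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()[:2]
            edges.append((int(u), int(v)))
        return MolecularGraph(edges, provenance=str(path.name))
    raise ValueError(f"unknown input format: {fmt!r}")
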