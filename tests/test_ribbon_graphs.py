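"""Builder invariants: vertex/edge counts, lattice validity, symmetry, io."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ring_basis_sizes
from wnrtools.ribbon_graphs import (
    MolecularGraph,
    ParameterError,
    RibbonSpec,
    build_parallelogram,
    build_wnr,
    build_znr,
    export_graph,
    read_graph,
)


@pytest.mark.parametrize(
    "r,c,nv,ne",
    [(1, 1, 6, 6), (2, 3, 22, 27), (3, 3, 30, 38)],
)
def test_parallelogram_counts(r, c, nv, ne):
    """M(r,c) has 2(rc+r+c) carbons and 3rc+2r+2c-1 bonds; the examples are
    fixed by Euler's relation (edges = vertices + hexagons - 1)."""
    mg = build_parallelogram(r, c)
    assert (mg.n_vertices, mg.n_edges) == (nv, ne)
    assert mg.n_edges == mg.n_vertices + r * c - 1


@pytest.mark.parametrize(
    "r,c,nv,ne",
    [(1, 1, 12, 13), (3, 3, 60, 79), (3, 4, 76, 101)],
)
def test_znr_counts(r, c, nv, ne):
    mg = build_znr(r, c)
    assert (mg.n_vertices, mg.n_edges) == (nv, ne)


@pytest.mark.parametrize(
    "r,c,n,nv",
    [(1, 1, 1, 12), (3, 4, 5, 380), (2, 2, 2, 64)],
)
def test_wnr_counts(r, c, n, nv):
    spec = RibbonSpec(r, c, n)
    mg = build_wnr(spec)
    assert mg.n_vertices == nv == spec.num_vertices
    assert mg.n_edges == spec.num_edges
    if (r, c, n) == (2, 2, 2):
        assert mg.n_edges == 82


def test_counts_match_closed_form_exhaustively():
    """Vertex/edge counts equal the family formulas for all r,c,n in 1..6."""
    for r, c, n in itertools.product(range(1, 7), repeat=3):
        spec = RibbonSpec(r, c, n)
        mg = build_wnr(spec)  # raises internally on count mismatch
        assert mg.n_vertices == spec.num_vertices
        assert mg.n_edges == spec.num_edges


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(1, 4), st.integers(1, 4), st.integers(1, 3))
def test_skeleton_invariants(r, c, n):
    """Every built ribbon is connected, bipartite, planar, has carbon
    degrees in {2, 3}, and all of its independent rings are hexagons."""
    mg = build_wnr(RibbonSpec(r, c, n))
    g = mg.graph
    assert nx.is_connected(g)
    assert nx.is_bipartite(g)
    assert set(dict(g.degree()).values()) <= {2, 3}
    sizes = ring_basis_sizes(mg)
    assert len(sizes) == mg.n_edges - mg.n_vertices + 1  # cyclomatic number
    assert set(sizes) == {6}


def test_znr_has_fixed_point_free_involution():
    """ZNR(r,c) is C2-symmetric: an order-2 automorphism without fixed
    vertices exists (consistent with all NMR classes having size 2)."""
    for r, c in [(1, 1), (2, 3), (3, 3)]:
        mg = build_znr(r, c)
        g = mg.graph
        gm = nx.isomorphism.GraphMatcher(g, g)
        found = False
        for mapping in gm.isomorphisms_iter():
            if any(mapping[v] == v for v in g):
                continue
            if all(mapping[mapping[v]] == v for v in g):
                found = True
                break
        assert found, f"no fixed-point-free involution for ZNR({r},{c})"


def test_wnr_n1_equals_znr():
    a = build_znr(2, 3)
    b = build_wnr(RibbonSpec(2, 3, 1))
    assert nx.utils.graphs_equal(a.graph, b.graph)


def test_bad_parameters_rejected():
    with pytest.raises(ParameterError):
        RibbonSpec(0, 1, 1)
    with pytest.raises(ParameterError):
        build_parallelogram(1, -2)


def test_vertex_order_is_lexicographic_and_deterministic():
    mg = build_wnr(RibbonSpec(2, 2, 2))
    coords = [tuple(row) for row in mg.coords]
    assert coords == sorted(coords)
    mg2 = build_wnr(RibbonSpec(2, 2, 2))
    assert np.array_equal(mg.coords, mg2.coords)
    assert np.array_equal(mg.edge_array(), mg2.edge_array())


# ----------------------------------------------------------------------
# io round trips
# ----------------------------------------------------------------------

def test_edgelist_export(tmp_path, hexagon):
    path = tmp_path / "hex.edgelist"
    export_graph(hexagon, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 6
    ids = {int(tok) for line in lines for tok in line.split()}
    assert ids == set(range(6))
    back = read_graph(path)
    assert nx.is_isomorphic(back.graph, hexagon.graph)


def test_xyz_export_is_all_carbon(tmp_path):
    mg = build_parallelogram(1, 1)
    path = tmp_path / "hex.xyz"
    export_graph(mg, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "6"
    atoms = lines[2:8]
    assert all(line.startswith("C ") for line in atoms)
    # nearest-neighbour distance = 1.42 A
    xyz = np.array([[float(x) for x in line.split()[1:]] for line in atoms])
    d01 = min(np.linalg.norm(xyz[0] - xyz[j]) for j in range(1, 6))
    assert d01 == pytest.approx(1.42, abs=1e-6)


def test_graphml_round_trip(tmp_path):
    mg = build_wnr(RibbonSpec(1, 1, 1))
    path = tmp_path / "wnr.graphml"
    export_graph(mg, path)
    back = read_graph(path)
    assert nx.is_isomorphic(back.graph, mg.graph)
    assert np.array_equal(back.coords, mg.coords)


def test_sdf_export_parses(tmp_path):
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    mg = build_parallelogram(1, 1)
    path = tmp_path / "hex.sdf"
    export_graph(mg, path)
    mol = next(Chem.SDMolSupplier(str(path), sanitize=False))
    assert mol.GetNumAtoms() == 6
    assert all(a.GetSymbol() == "C" for a in mol.GetAtoms())


def test_unknown_format_rejected(tmp_path, hexagon):
    with pytest.raises(ValueError):
        export_graph(hexagon, tmp_path / "x.foo", "foo")
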