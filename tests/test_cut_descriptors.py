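"""Cut-method engine: Theta*-classes, descriptors, and the independent
distance-sum oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wnrtools.cut_descriptors import (
    NotPartialCubeError,
    all_pairs_distances,
    distance_indices,
    gutman_oracle,
    indices_from_classes,
    schultz_oracle,
    theta_classes,
    wiener_oracle,
)
from wnrtools.ribbon_graphs import MolecularGraph, RibbonSpec, build_wnr


def test_distances_hexagon(hexagon):
    d = all_pairs_distances(hexagon)
    assert d.max() == 3
    assert d.dtype == np.int16
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0)


def test_distances_path(path3):
    d = all_pairs_distances(path3)
    assert d[0, 2] == 2


def test_disconnected_input_names_components():
    mg = MolecularGraph([(0, 1), (2, 3)])
    with pytest.raises(ValueError, match="components"):
        all_pairs_distances(mg)


def test_theta_classes_hexagon(hexagon):
    """The 6-cycle has three cuts of two opposite edges, each splitting the
    ring into 3 + 3 vertices."""
    cls = theta_classes(hexagon)
    assert len(cls) == 3
    for tc in cls:
        assert tc.size == 2
        assert (tc.n1, tc.n2) == (3, 3)
        assert (tc.m1, tc.m2) == (2, 2)


def test_theta_classes_biphenyl(biphenyl):
    """WNR(1,1,1): six two-edge ring cuts plus the bridge as a singleton
    class with a balanced 6|6 split."""
    cls = theta_classes(biphenyl)
    assert len(cls) == 7
    sizes = sorted(tc.size for tc in cls)
    assert sizes == [1, 2, 2, 2, 2, 2, 2]
    bridge = [tc for tc in cls if tc.size == 1][0]
    assert (bridge.n1, bridge.n2) == (6, 6)


def test_theta_class_invariants(wnr222):
    cls = theta_classes(wnr222)
    n, m = wnr222.n_vertices, wnr222.n_edges
    assert sum(tc.size for tc in cls) == m
    for tc in cls:
        assert tc.n1 + tc.n2 == n
        assert tc.m1 + tc.m2 == m - tc.size


def test_coupling_classes_of_wide_ribbon():
    """In WNR(4,6,2) the coupling cuts have exactly r = 4 edges and cut off
    whole parallelogram prefixes: n1 = 2(2j-1)(cr+c+r) for the in-unit
    couplings and 4j(cr+c+r) for the between-unit coupling."""
    r, c, n = 4, 6, 2
    mg = build_wnr(RibbonSpec(r, c, n))
    half = c * r + c + r  # vertices per parallelogram / 2
    cls = theta_classes(mg)
    splits = {min(tc.n1, tc.n2) for tc in cls if tc.size == r}
    for j in (1, 2):
        assert min(2 * (2 * j - 1) * half,
                   mg.n_vertices - 2 * (2 * j - 1) * half) in splits
    assert 4 * 1 * half in splits


def test_distance_indices_known_values(biphenyl, wnr222):
    idx1 = distance_indices(biphenyl)
    assert idx1["W"] == 198
    assert idx1["PI"] == 144
    idx2 = distance_indices(wnr222)
    assert idx2["W"] == 16988
    assert idx2["Sze"] == 81660


def test_hexagon_indices(hexagon):
    idx = distance_indices(hexagon)
    assert idx["W"] == 27
    assert idx["Mov"] == 0
    assert idx["Moe"] == 0


def test_oracles_on_hexagon(hexagon):
    d = all_pairs_distances(hexagon)
    assert wiener_oracle(d) == 27
    assert schultz_oracle(hexagon, d) == 4 * 27  # all degrees 2
    assert gutman_oracle(hexagon, d) == 4 * 27


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(1, 3), st.integers(1, 3), st.integers(1, 3))
def test_cut_method_equals_direct_summation(r, c, n):
    """W, S and Gut assembled from Theta*-cuts equal their definitions as
    degree-weighted distance sums, for every ribbon in the sampled box."""
    mg = build_wnr(RibbonSpec(r, c, n))
    d = all_pairs_distances(mg)
    idx = distance_indices(mg, d)
    assert idx["W"] == wiener_oracle(d)
    assert idx["S"] == schultz_oracle(mg, d)
    assert idx["Gut"] == gutman_oracle(mg, d)
    # PI bound and class-size conservation
    m = mg.n_edges
    assert idx["PI"] <= m * (m - 1)


def test_non_partial_cube_refused():
    """K4 is not a partial cube; the engine must refuse it rather than
    report wrong cut-method values."""
    k4 = MolecularGraph([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
    with pytest.raises(NotPartialCubeError):
        theta_classes(k4)


def test_wev_integrality_guard(hexagon):
    cls = theta_classes(hexagon)
    idx = indices_from_classes(cls, 6, 6)
    assert idx["Wev"] * 2 == sum(tc.n1 * tc.m2 + tc.n2 * tc.m1 for tc in cls)
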