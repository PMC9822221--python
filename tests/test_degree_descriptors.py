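"""Degree / degree-sum partitions and the bond-additive functionals."""

import itertools
import math

import pytest

from wnrtools.degree_descriptors import (
    DESCRIPTOR_FUNCTIONS,
    all_degree_indices,
    ch_bond_count,
    degree_partition,
    degree_sum_partition,
    degree_two_count,
    evaluate_descriptor,
    table_degree_partition,
    table_degree_sum_partition,
)
from wnrtools.ribbon_graphs import RibbonSpec, build_wnr


def test_hexagon_partitions(hexagon):
    assert dict(degree_partition(hexagon)) == {(2, 2): 6}
    assert dict(degree_sum_partition(hexagon)) == {(4, 4): 6}


def test_biphenyl_partitions(biphenyl):
    assert dict(degree_partition(biphenyl)) == {(2, 2): 8, (2, 3): 4, (3, 3): 1}
    assert dict(degree_sum_partition(biphenyl)) == {
        (5, 7): 4, (4, 5): 4, (4, 4): 4, (7, 7): 1,
    }


def test_partition_counts_sum_to_edges(wnr222):
    assert sum(degree_partition(wnr222).values()) == wnr222.n_edges == 82
    assert sum(degree_sum_partition(wnr222).values()) == 82


def test_degree_partition_matches_family_formulas():
    """Directly computed degree partitions equal the closed-form bond
    counts for all 1 <= r,c,n <= 6."""
    for r, c, n in itertools.product(range(1, 7), repeat=3):
        mg = build_wnr(RibbonSpec(r, c, n))
        assert dict(degree_partition(mg)) == table_degree_partition(r, c, n), (r, c, n)


def test_degree_sum_partition_matches_family_formulas_from_two():
    """The ten-class degree-sum closed forms hold for r,c,n >= 2 (at n = 1
    some closed-form counts go negative and the forms are invalid)."""
    for r, c, n in itertools.product(range(2, 5), repeat=3):
        mg = build_wnr(RibbonSpec(r, c, n))
        assert dict(degree_sum_partition(mg)) == table_degree_sum_partition(r, c, n)


def test_degree_sum_closed_form_invalid_at_n1_is_detected(biphenyl):
    """Direct degree-sum M2 on WNR(1,1,1) is 333; the closed form yields
    297 — the discrepancy must be visible, not patched."""
    direct = evaluate_descriptor(degree_sum_partition(biphenyl), "M2")
    assert direct == 333
    closed = sum(cnt * s * t
                 for (s, t), cnt in table_degree_sum_partition(1, 1, 1).items())
    assert closed == 297
    assert direct != closed


def test_evaluate_descriptor_examples(hexagon, biphenyl):
    assert evaluate_descriptor(degree_partition(hexagon), "M1") == 24
    assert evaluate_descriptor(degree_partition(biphenyl), "M2") == 65
    assert evaluate_descriptor(degree_sum_partition(biphenyl), "M1") == 130
    # cross-check of the 130: 4*12 + 4*9 + 4*8 + 14
    assert 4 * 12 + 4 * 9 + 4 * 8 + 14 == 130


def test_m1_three_ways(wnr222):
    """Partition sum, sum of squared degrees, and the closed form agree."""
    part_sum = evaluate_descriptor(degree_partition(wnr222), "M1")
    sq = int(sum(d * d for d in wnr222.degrees()))
    r = c = n = 2
    closed = 36 * c * n * r + 16 * c * n + 36 * n * r - 10 * r - 20 * n
    assert part_sum == sq == closed == 436


def test_az_domain_error():
    from collections import Counter
    part = Counter({(1, 1): 1})
    with pytest.raises(ValueError):
        evaluate_descriptor(part, "AZ")


def test_descriptor_functions_symmetric_positive():
    for name, fn in DESCRIPTOR_FUNCTIONS.items():
        for s, t in [(2, 2), (2, 3), (3, 3), (4, 9)]:
            assert fn(s, t) == pytest.approx(fn(t, s)), name
            assert fn(s, t) > 0, name


def test_ch_bond_count_formula_and_skeleton_count():
    """The family closed form 2(2cn+r) differs from the skeleton's
    degree-2 carbon count 4cn+4n+2r by 4n; both are exposed."""
    for r, c, n in [(1, 1, 1), (3, 3, 1), (2, 3, 4)]:
        spec = RibbonSpec(r, c, n)
        mg = build_wnr(spec)
        assert ch_bond_count(spec) == 2 * (2 * c * n + r)
        assert degree_two_count(mg) == 4 * c * n + 4 * n + 2 * r
    # generic graph: hexagon path has six degree-2 carbons
    from wnrtools.ribbon_graphs import build_parallelogram
    assert degree_two_count(build_parallelogram(1, 1)) == 6


def test_all_degree_indices_consistency(znr33):
    vals = all_degree_indices(znr33, "degree")
    part = degree_partition(znr33)
    assert vals["F"] == evaluate_descriptor(part, lambda s, t: s * s + t * t)
    assert vals["SO"] == pytest.approx(
        sum(cnt * math.hypot(s, t) for (s, t), cnt in part.items())
    )
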