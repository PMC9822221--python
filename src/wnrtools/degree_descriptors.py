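"""Degree / degree-sum edge partitions and bond-additive descriptors.

An edge ``uv`` is labelled either by the (sorted) pair of skeleton degrees
``(d_u, d_v)`` or by the pair of neighbourhood degree sums
``(s_u, s_v)`` with ``s_v = sum of deg(w) over carbon neighbours w of v``.
A descriptor is then ``psi(G) = sum over label pairs (s,t) of
count(s,t) * psi(s,t)`` for one of the eleven functionals below.

=======  =============================  =================================
name     psi(s, t)                      common name
=======  =============================  =================================
M1       s + t                          first Zagreb
M2       s * t                          second Zagreb
SO       sqrt(s^2 + t^2)                Sombor
SC       1 / sqrt(s + t)                sum-connectivity
GA       2 sqrt(st) / (s + t)           geometric-arithmetic
AZ       (st / (s + t - 2))^3           augmented Zagreb
ISI      st / (s + t)                   inverse sum indeg
ABC      sqrt((s + t - 2) / (st))       atom-bond connectivity
F        s^2 + t^2                      forgotten
SDD      s/t + t/s                      symmetric division of degrees
H        2 / (s + t)                    harmonic
=======  =============================  =================================

Degrees and degree sums are evaluated on the hydrogen-suppressed carbon
skeleton only.  C–H bond counts are reported separately and never enter
the descriptor sums.
"""

from __future__ import annotations

import math
from collections import Counter

from wnrtools.ribbon_graphs import MolecularGraph, RibbonSpec

__all__ = [
    "DESCRIPTOR_FUNCTIONS",
    "degree_partition",
    "degree_sum_partition",
    "evaluate_descriptor",
    "all_degree_indices",
    "table_degree_partition",
    "table_degree_sum_partition",
    "ch_bond_count",
    "degree_two_count",
]

DESCRIPTOR_FUNCTIONS = {
    "M1": lambda s, t: s + t,
    "M2": lambda s, t: s * t,
    "SO": lambda s, t: math.sqrt(s * s + t * t),
    "SC": lambda s, t: 1.0 / math.sqrt(s + t),
    "GA": lambda s, t: 2.0 * math.sqrt(s * t) / (s + t),
    "AZ": lambda s, t: (s * t / (s + t - 2.0)) ** 3,
    "ISI": lambda s, t: s * t / (s + t),
    "ABC": lambda s, t: math.sqrt((s + t - 2.0) / (s * t)),
    "F": lambda s, t: s * s + t * t,
    "SDD": lambda s, t: s / t + t / s,
    "H": lambda s, t: 2.0 / (s + t),
}


def _partition(mg: MolecularGraph, labels) -> Counter:
    out: Counter = Counter()
    for u, v in mg.edge_array():
        s, t = labels[u], labels[v]
        out[(min(s, t), max(s, t))] += 1
    return out


def degree_partition(mg: MolecularGraph) -> Counter:
    """Edge counts by sorted endpoint-degree pair (s, t)."""
    return _partition(mg, mg.degrees())


def degree_sum_partition(mg: MolecularGraph) -> Counter:
    """Edge counts by sorted endpoint neighbourhood-degree-sum pair."""
    deg = mg.degrees()
    g = mg.graph
    ds = [int(sum(deg[w] for w in g[v])) for v in range(mg.n_vertices)]
    return _partition(mg, ds)


def evaluate_descriptor(partition: Counter, fn) -> float:
    """Weighted sum of psi over an edge partition.

    ``fn`` may be a callable psi(s, t) or one of the names in
    :data:`DESCRIPTOR_FUNCTIONS`.  The augmented Zagreb functional is
    undefined at s + t = 2 (cannot occur on carbon skeletons).
    """
    if isinstance(fn, str):
        name = fn
        fn = DESCRIPTOR_FUNCTIONS[fn]
    else:
        name = getattr(fn, "__name__", "psi")
    total = 0.0
    for (s, t), cnt in sorted(partition.items()):
        if name == "AZ" and s + t <= 2:
            raise ValueError("augmented Zagreb undefined for an edge with s+t <= 2")
        total += cnt * fn(s, t)
    return total


def all_degree_indices(mg: MolecularGraph, mode: str = "degree") -> dict[str, float]:
    """All eleven descriptors for the chosen labelling mode.

    mode = 'degree' or 'degree-sum'.
    """
    if mode == "degree":
        part = degree_partition(mg)
    elif mode == "degree-sum":
        part = degree_sum_partition(mg)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {name: evaluate_descriptor(part, name) for name in DESCRIPTOR_FUNCTIONS}


# ----------------------------------------------------------------------
# closed-form partitions for the ribbon family
# ----------------------------------------------------------------------

def table_degree_partition(r: int, c: int, n: int) -> dict[tuple[int, int], int]:
    """Closed-form degree partition of WNR(r, c, n): counts of the
    (2,2), (2,3) and (3,3) bond classes."""
    part = {
        (2, 2): 4 * (n + 1),
        (2, 3): 4 * (2 * c * n + r - 2),
        (3, 3): 6 * c * n * r + 6 * n * r - 4 * c * n - 5 * r - 6 * n + 4,
    }
    return {k: v for k, v in part.items() if v != 0}


def table_degree_sum_partition(r: int, c: int, n: int) -> dict[tuple[int, int], int]:
    """Closed-form degree-sum partition of WNR(r, c, n) (ten bond classes).

    Several count formulas go negative for n = 1 (and small r, c); the
    closed form is only meaningful for r, c, n >= 2.  Callers should
    validate against :func:`degree_sum_partition` and report rather than
    assume (see docs/methods.md).
    """
    part = {
        (4, 5): 4,
        (5, 5): 4 * n,
        (5, 7): 2 * (2 * n + 3),
        (5, 8): 2 * (2 * n - 1),
        (6, 8): 2 * (2 * n - 1),
        (6, 7): 2 * (4 * c * n + 2 * r - 6 * n - 5),
        (7, 9): 2 * (2 * c * n - 2 * n + r - 1),
        (8, 8): 2 * (2 * n - 1),
        (8, 9): 4 * (2 * n - 1),
        (9, 9): 6 * c * n * r + 6 * n * r - 8 * c * n - 7 * r - 14 * n + 12,
    }
    return {k: v for k, v in part.items() if v != 0}


def ch_bond_count(spec: RibbonSpec) -> int:
    """Closed-form C-H bond count 2(2cn + r) of the ribbon family.

    Note: this published closed form does NOT equal the number of
    degree-2 carbons of the skeleton, which is 4cn + 4n + 2r (every
    degree-2 carbon bears one H).  Use :func:`degree_two_count` for the
    skeleton-derived value; the discrepancy 4n is reported by the table
    regeneration tooling rather than silently patched.
    """
    return 2 * (2 * spec.c * spec.n + spec.r)


def degree_two_count(mg: MolecularGraph) -> int:
    """Number of degree-2 carbons (= implicit H count) of a skeleton."""
    return int((mg.degrees() == 2).sum())
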