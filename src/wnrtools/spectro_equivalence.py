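"""DDSV vertex equivalence, ¹³C NMR signal patterns and ESR generating
functions.

The distance degree sequence vector (DDSV) of vertex i is
``(D_i0, D_i1, ..., D_ip)`` where ``D_ij`` counts vertices at distance j
from i (``D_i0 = 1``, ``D_i1 = deg i``, entries sum to N).  Vertices with
identical DDSV (zero-padded to the graph diameter) are candidates for
chemically equivalent carbons: the number of DDSV classes is the
predicted number of ¹³C NMR signals and the class sizes give the
intensity pattern.  Automorphism orbits always refine DDSV classes
(automorphic vertices share every distance statistic), but the converse
can fail; the orbit partition is exposed as an independent oracle.

For an S = 1/2 radical whose q equivalence classes contain
``k_1 .. k_q`` spin-1/2 nuclei, the ESR hyperfine generating function is
``prod_i (alpha_i + beta_i)^{k_i}``: each class contributes a binomial
(k_i + 1)-line multiplet with intensities C(k_i, 0..k_i), the composed
pattern has ``prod (k_i + 1)`` lines, and the intensities conserve total
weight ``2^(sum k_i)``.  Coupling magnitudes are outside the model, so
the composed pattern is purely combinatorial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from wnrtools.cut_descriptors import all_pairs_distances
from wnrtools.ribbon_graphs import MolecularGraph

__all__ = [
    "EquivalencePartition",
    "HyperfinePattern",
    "ddsv",
    "nmr_partition",
    "automorphism_orbit_oracle",
    "esr_pattern",
]


@dataclass(frozen=True)
class EquivalencePartition:
    """Disjoint vertex classes covering 0..N-1, each sorted, ordered by
    (size, smallest member)."""

    classes: tuple[tuple[int, ...], ...]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.classes)

    def intensity_pattern(self) -> tuple[int, ...]:
        """NMR intensity ratios = sorted class sizes."""
        return tuple(sorted(self.sizes))

    def refines_or_equals(self, coarser: "EquivalencePartition") -> bool:
        """True if every class of self lies inside one class of coarser."""
        lookup = {}
        for idx, cls in enumerate(coarser.classes):
            for v in cls:
                lookup[v] = idx
        return all(len({lookup[v] for v in cls}) == 1 for cls in self.classes)


def ddsv(mg: MolecularGraph, dist: np.ndarray | None = None) -> list[tuple[int, ...]]:
    """Distance degree sequence vector of every vertex (variable length,
    up to the vertex eccentricity)."""
    if dist is None:
        dist = all_pairs_distances(mg)
    out = []
    for i in range(mg.n_vertices):
        row = dist[i]
        ecc = int(row.max())
        counts = np.bincount(row.astype(np.int64), minlength=ecc + 1)
        out.append(tuple(int(x) for x in counts))
    return out


def nmr_partition(
    mg: MolecularGraph, dist: np.ndarray | None = None
) -> EquivalencePartition:
    """Vertex classes of identical DDSV; class count = predicted number of
    ¹³C NMR signals."""
    vecs = ddsv(mg, dist)
    diam = max(len(v) for v in vecs)
    padded = [v + (0,) * (diam - len(v)) for v in vecs]
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(padded):
        groups.setdefault(key, []).append(i)
    classes = sorted((tuple(sorted(g)) for g in groups.values()),
                     key=lambda c: (len(c), c[0]))
    return EquivalencePartition(classes=tuple(classes))


def automorphism_orbit_oracle(mg: MolecularGraph) -> EquivalencePartition:
    """Automorphism orbits of the graph (independent symmetry oracle).

    VF2 self-isomorphism enumeration, pruned by using the DDSV signature
    as a node invariant (any automorphism preserves it).  Orbits must
    refine-or-equal the DDSV partition.
    """
    g = mg.graph
    vecs = ddsv(mg)
    sig = {i: v for i, v in enumerate(vecs)}
    nx.set_node_attributes(g, sig, "_ddsv_sig")
    try:
        gm = nx.isomorphism.GraphMatcher(
            g, g, node_match=lambda a, b: a["_ddsv_sig"] == b["_ddsv_sig"]
        )
        parent = list(range(mg.n_vertices))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for mapping in gm.isomorphisms_iter():
            for u, v in mapping.items():
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
        groups: dict[int, list[int]] = {}
        for i in range(mg.n_vertices):
            groups.setdefault(find(i), []).append(i)
    finally:
        for v in g.nodes():
            g.nodes[v].pop("_ddsv_sig", None)
    classes = sorted((tuple(sorted(grp)) for grp in groups.values()),
                     key=lambda cls: (len(cls), cls[0]))
    return EquivalencePartition(classes=tuple(classes))


@dataclass(frozen=True)
class HyperfinePattern:
    """ESR hyperfine structure from equivalent spin-1/2 nucleus classes."""

    class_sizes: tuple[int, ...]
    multiplets: tuple[tuple[int, ...], ...]  # per-class binomial intensities
    total_lines: int                          # prod (k_i + 1), exact
    n_spins: int                              # sum k_i
    intensities: tuple[int, ...] | None       # composed; None if above cap

    @property
    def total_weight(self) -> int:
        """2**n_spins; composed intensities must sum to this."""
        return 2 ** self.n_spins


def esr_pattern(
    partition: EquivalencePartition, expansion_cap: int = 10**6
) -> HyperfinePattern:
    """Hyperfine pattern of spin-1/2 nuclei grouped by equivalence class.

    Classes couple in a fixed order (size, then smallest member — the
    class order of the partition); the composed intensity vector is the
    sequential-splitting expansion and is materialized only when the line
    count ``prod (k_i + 1)`` does not exceed ``expansion_cap``.
    """
    sizes = partition.sizes
    multiplets = tuple(
        tuple(math.comb(k, j) for j in range(k + 1)) for k in sizes
    )
    total_lines = math.prod(k + 1 for k in sizes)
    n_spins = sum(sizes)
    # sequential splitting with distinct couplings: every class splits every
    # existing line, so the composed vector is the outer product (a plain
    # convolution would merge coincidentally overlapping positions).
    intensities = _compose_distinct(multiplets) if total_lines <= expansion_cap else None
    return HyperfinePattern(
        class_sizes=sizes,
        multiplets=multiplets,
        total_lines=total_lines,
        n_spins=n_spins,
        intensities=intensities,
    )


def _compose_distinct(multiplets) -> tuple[int, ...]:
    """Tensor (outer) composition of the per-class multiplets: every class
    splits every existing line, couplings assumed pairwise distinct."""
    acc = [1]
    for mult in multiplets:
        acc = [a * m for a in acc for m in mult]
    return tuple(acc)
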