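"""Hückel-level spectral and energetic analysis of carbon skeletons.

The tight-binding (Hückel) pi-orbital energies of an alternant hydrocarbon
are the eigenvalues of the adjacency matrix, in units of the resonance
integral beta (beta > 0; larger eigenvalue = more bonding).  For a
skeleton with N carbons at half filling:

* HOMO–LUMO gap = lambda_{N/2} - lambda_{N/2+1} of the descending
  spectrum (twice the smallest non-negative eigenvalue for alternants);
* total pi-electron energy  E_pi = 2 * sum of positive eigenvalues;
* delocalization energy per site = E_pi/N - 1 (relative to N isolated
  pi electrons at alpha + beta each, i.e. ethylene-like reference);
* Kekulé count K = number of perfect matchings; for benzenoid-type
  skeletons (no 4k-rings) K^2 = |det A|;
* Herndon resonance energy per site = 1.185 ln(K) / N (beta units).

All per-"site" energies here are normalized per carbon vertex, which at
half filling equals per pi-electron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from wnrtools.ribbon_graphs import MolecularGraph

__all__ = [
    "SpectralSummary",
    "adjacency_spectrum",
    "homo_lumo_gap",
    "pi_energies",
    "kekule_count",
    "kekule_count_dp",
    "resonance_energy_per_site",
    "spectral_summary",
]

#: Herndon's empirical proportionality between resonance energy and ln K,
#: in units of beta.
HERNDON_FACTOR = 1.185

#: Vertex count up to which the determinant route is always cross-checked
#: against the exact matching-count DP.
CROSS_CHECK_LIMIT = 40


@dataclass(frozen=True)
class SpectralSummary:
    """Spectral/energetic summary of one skeleton (energies in beta)."""

    eigenvalues: tuple[float, ...]       # descending
    homo_lumo_gap: float
    e_pi_total: float
    e_pi_per_site: float
    e_deloc_per_site: float
    kekule_count: int
    re_per_site: float | None            # None when K = 0


def adjacency_spectrum(mg: MolecularGraph) -> np.ndarray:
    """Adjacency eigenvalues sorted in descending order."""
    ev = np.linalg.eigvalsh(mg.adjacency_matrix())
    return ev[::-1].copy()


def homo_lumo_gap(spectrum: np.ndarray) -> float:
    """Gap between the two middle orbitals of a half-filled even system."""
    n = len(spectrum)
    if n % 2:
        raise ValueError("HOMO-LUMO gap at half filling needs an even vertex count")
    gap = float(spectrum[n // 2 - 1] - spectrum[n // 2])
    return abs(gap)


def pi_energies(spectrum: np.ndarray, n_vertices: int) -> tuple[float, float]:
    """(E_pi per site, delocalization energy per site) from the spectrum."""
    e_pi = 2.0 * float(np.sum(spectrum[spectrum > 0]))
    per_site = e_pi / n_vertices
    return per_site, per_site - 1.0


def kekule_count_dp(mg: MolecularGraph, order: list[int] | None = None) -> int:
    """Exact number of perfect matchings by boundary dynamic programming.

    Vertices are eliminated in id order (lexicographic lattice order for
    built ribbons, which keeps the matched-boundary state set small); the
    state is the set of already-matched not-yet-eliminated vertices.
    Exact for any graph, exponential only in the boundary width.
    """
    g = mg.graph
    nodes = order if order is not None else sorted(g.nodes())
    pos = {u: i for i, u in enumerate(nodes)}
    states: dict[frozenset, int] = {frozenset(): 1}
    for i, u in enumerate(nodes):
        nxt: dict[frozenset, int] = {}
        for st, cnt in states.items():
            if u in st:
                s2 = st - {u}
                nxt[s2] = nxt.get(s2, 0) + cnt
            else:
                for v in g[u]:
                    if pos[v] > i and v not in st:
                        s2 = st | {v}
                        nxt[s2] = nxt.get(s2, 0) + cnt
        states = nxt
        if not states:
            return 0
    return states.get(frozenset(), 0)


def kekule_count(mg: MolecularGraph, method: str = "auto") -> int:
    """Number of Kekulé structures (perfect matchings) of the skeleton.

    method='det' uses K = round(sqrt(|det A|)), valid for benzenoid-type
    alternants where all matchings carry equal sign; method='dp' runs the
    exact matching counter.  The default 'auto' uses the determinant and,
    for graphs up to 40 vertices, cross-checks it against the DP; any
    disagreement raises, since it signals a non-benzenoid input.
    """
    if mg.n_vertices % 2:
        return 0
    if method == "dp":
        return kekule_count_dp(mg)
    a = mg.adjacency_matrix()
    sign, logabsdet = np.linalg.slogdet(a)
    k_det = 0 if np.isinf(logabsdet) else round(math.exp(0.5 * logabsdet))
    if method == "det":
        return k_det
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if mg.n_vertices <= CROSS_CHECK_LIMIT:
        k_dp = kekule_count_dp(mg)
        if k_dp != k_det:
            raise ArithmeticError(
                f"determinant Kekulé count {k_det} disagrees with exact "
                f"matching count {k_dp}; input is not benzenoid-like"
            )
        return k_dp
    return k_det


def resonance_energy_per_site(k: int, n_vertices: int) -> float:
    """Herndon resonance energy 1.185 ln(K) / N in beta units (K >= 1)."""
    if k < 1:
        raise ValueError(
            "resonance energy is undefined for K = 0 (no Kekulé structure)"
        )
    return HERNDON_FACTOR * math.log(k) / n_vertices


def spectral_summary(mg: MolecularGraph, kekule_method: str = "auto") -> SpectralSummary:
    """Full spectral/energetic report for one skeleton."""
    spec = adjacency_spectrum(mg)
    n = mg.n_vertices
    gap = homo_lumo_gap(spec)
    per_site, deloc = pi_energies(spec, n)
    k = kekule_count(mg, method=kekule_method)
    re = resonance_energy_per_site(k, n) if k >= 1 else None
    return SpectralSummary(
        eigenvalues=tuple(float(x) for x in spec),
        homo_lumo_gap=gap,
        e_pi_total=per_site * n,
        e_pi_per_site=per_site,
        e_deloc_per_site=deloc,
        kekule_count=k,
        re_per_site=re,
    )
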