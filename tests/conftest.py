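import networkx as nx
import pytest

from wnrtools.ribbon_graphs import MolecularGraph, RibbonSpec, build_wnr, build_znr


@pytest.fixture(scope="session")
def hexagon() -> MolecularGraph:
    """Benzene skeleton: the 6-cycle."""
    return MolecularGraph([(i, (i + 1) % 6) for i in range(6)],
                          provenance="hexagon")


@pytest.fixture(scope="session")
def path3() -> MolecularGraph:
    """Path on three vertices (allyl-like test graph)."""
    return MolecularGraph([(0, 1), (1, 2)], provenance="path3")


@pytest.fixture(scope="session")
def biphenyl() -> MolecularGraph:
    """WNR(1,1,1): two hexagons joined by one bond."""
    return build_wnr(RibbonSpec(1, 1, 1))


@pytest.fixture(scope="session")
def znr22() -> MolecularGraph:
    return build_znr(2, 2)


@pytest.fixture(scope="session")
def znr33() -> MolecularGraph:
    return build_znr(3, 3)


@pytest.fixture(scope="session")
def wnr222() -> MolecularGraph:
    return build_wnr(RibbonSpec(2, 2, 2))


def ring_basis_sizes(mg: MolecularGraph) -> list[int]:
    """Cycle lengths of a minimum cycle basis (the independent rings)."""
    assert nx.check_planarity(mg.graph)[0], "ribbon skeletons must be planar"
    return sorted(len(cyc) for cyc in nx.minimum_cycle_basis(mg.graph))
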