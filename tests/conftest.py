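import numpy as np
import pytest

from convergescan.rer import RateMatrix
from convergescan.trees import ElementTree, MasterTree


@pytest.fixture
def master4():
    """Four-taxon master ((A,B),(C,D)) with unit-scale branch lengths."""
    return MasterTree("((A:1,B:2):0.5,(C:3,D:4):1.5);")


@pytest.fixture
def master2():
    return MasterTree("(A:1,B:2);")


def make_element(master: MasterTree, taxa, lengths_by_taxonset) -> ElementTree:
    """Build an ElementTree with explicit per-branch lengths.

    ``lengths_by_taxonset`` maps iterable taxon sets (the child clade of
    each induced branch) to lengths; keys not supplied default to 1.0.
    """
    taxa = frozenset(taxa)
    supplied = {frozenset(k): v for k, v in lengths_by_taxonset.items()}
    lengths = {}
    for key in master.branch_paths(taxa):
        lengths[key] = float(supplied.get(key, 1.0))
    return ElementTree(element_id="e", taxa=taxa, lengths=lengths)


@pytest.fixture
def small_sim():
    """A small planted-signal simulation shared across tests."""
    from convergescan.simulate import SimulationConfig, simulate_element_trees

    return simulate_element_trees(
        SimulationConfig(n_taxa=16, n_elements=120, min_species=8, seed=42)
    )
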