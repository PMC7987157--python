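import numpy as np
import pytest

from srpasr.evomodel import wag_model
from srpasr.seqio import Alignment
from srpasr.simulate import SimulationScenario, simulate_alignment, simulate_tree
from srpasr.tree import PhyloTree


@pytest.fixture(scope="session")
def wag():
    return wag_model()


@pytest.fixture(scope="session")
def duplication_bundle(wag):
    """Small synthetic duplication-tree dataset with structured gaps.

    FtsY-side sequences carry a shared 15-column N-terminal deletion, so the
    alignment has the column-structured gap pattern the pipeline expects.
    """
    scen = SimulationScenario(n_taxa_per_clade=4, branch_scale=0.2, length=120, seed=7)
    tree = simulate_tree(scen)
    aln, root_seq = simulate_alignment(tree, wag, 120, seed=7)
    records = []
    for header, seq in aln:
        if header.startswith("FtsY"):
            seq = "-" * 15 + seq[15:]
        records.append((header, seq))
    return tree, Alignment(records), root_seq


@pytest.fixture()
def star3():
    """3-leaf star tree with branch length 0.1."""
    return PhyloTree.from_newick(
        "(Ffh_Bacteria_P_a1:0.1,Ffh_Bacteria_P_a2:0.1,Ffh_Bacteria_P_a3:0.1);")


def make_alignment(tree_or_names, columns):
    """Build an alignment from per-column character strings.

    ``columns`` is a list of strings, one character per leaf, in leaf order.
    """
    names = (tree_or_names.leaf_names() if isinstance(tree_or_names, PhyloTree)
             else list(tree_or_names))
    seqs = ["".join(col[i] for col in columns) for i in range(len(names))]
    return Alignment(list(zip(names, seqs)))
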