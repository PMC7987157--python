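"""Synthetic data generation and the WAG-simulation composition null.

The generator emulates the structure of the real study system: a rooted tree
whose root is a gene duplication joining two paralog subtrees (Ffh-like and
FtsY-like), each containing a bacterial and an archaeal clade; sequences
evolved along the tree under the WAG model; and column-structured gaps taken
from an empirical (or synthetic) template alignment rather than simulated
stochastically.  Root residue frequencies are configurable so scenarios with
depleted late-code amino acids (Cys, His, Phe, Met, Tyr, Trp) can be built.

The null arm mirrors the composition analysis: for each simulation, tip
sequences are drawn from the model (so their composition reflects WAG
equilibrium), the empirical gap pattern is overlaid, one reduced dataset is
assembled (one random member per cluster), the guide tree is pruned, and the
root is reconstructed and thresholded; the per-simulation amino-acid counts
form the null distribution against which the observed ancestral counts are
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .asr import call_sequence, reconstruct
from .errors import AlignmentError, DomainError
from .evomodel import RateModel, transition_probs
from .resample import ClusterSet, prune_tree
from .seqio import AA_INDEX, AA_ORDER, GAP, Alignment, ungapped_length
from .tree import Node, PhyloTree

__all__ = [
    "SimulationScenario", "NullDistribution", "simulate_tree",
    "simulate_alignment", "overlay_gaps", "null_reconstruction_distribution",
    "LATE_AMINO_ACIDS", "depleted_root_freqs",
]

#: The six residues inferred to have entered the genetic code last.
LATE_AMINO_ACIDS = "CHFMYW"


def depleted_root_freqs(model: RateModel, residues: str = LATE_AMINO_ACIDS,
                        factor: float = 10.0) -> np.ndarray:
    """Model equilibrium frequencies with ``residues`` divided by ``factor``,
    renormalised."""
    freqs = model.eq_freqs.copy()
    for r in residues:
        freqs[AA_INDEX[r]] /= factor
    return freqs / freqs.sum()


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic dataset."""

    n_taxa_per_clade: int = 8
    tree_shape: str = "balanced"          # balanced | birth_death | supplied
    branch_scale: float = 0.3             # substitutions/site per branch
    duplication_at_root: bool = True
    length: int = 400
    root_freqs: Optional[np.ndarray] = None   # default: model eq_freqs
    gap_template: Optional[Alignment] = None
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise DomainError("length must be >= 1")
        if self.n_taxa_per_clade < 1:
            raise DomainError("n_taxa_per_clade must be >= 1")
        if self.root_freqs is not None:
            rf = np.asarray(self.root_freqs, dtype=float)
            if rf.shape != (20,) or abs(rf.sum() - 1.0) > 1e-12 or np.any(rf < 0):
                raise DomainError("root_freqs must be 20 probabilities summing to 1")
            self.root_freqs = rf


@dataclass
class NullDistribution:
    amino_acid: str
    node_id: str
    counts: np.ndarray
    #: ungapped length of the called ancestral sequence in each simulation
    root_lengths: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise DomainError("null counts must be non-negative")

    @property
    def n_sims(self) -> int:
        return len(self.counts)


def _balanced_clade(n_taxa: int, scale: float, prefix: str, rng) -> Node:
    """Balanced-ish bifurcating clade over n_taxa leaves, branch length ~scale."""
    leaves = [Node(name=f"{prefix}{i:03d}", length=_blen(scale, rng)) for i in range(n_taxa)]
    level = leaves
    while len(level) > 1:
        nxt = []
        for i in range(0, len(level) - 1, 2):
            parent = Node(length=_blen(scale, rng))
            parent.add(level[i])
            parent.add(level[i + 1])
            nxt.append(parent)
        if len(level) % 2:
            nxt.append(level[-1])
        level = nxt
    clade = level[0]
    return clade


def _blen(scale: float, rng) -> float:
    # deterministic given the stream; strictly positive
    return float(scale * (0.5 + rng.random()))


def _birth_death_clade(n_taxa: int, scale: float, prefix: str, rng) -> Node:
    """Yule-style clade: repeatedly split a random pending lineage."""
    root = Node(length=_blen(scale, rng))
    pending = [root]
    while len(pending) < n_taxa:
        node = pending.pop(rng.integers(len(pending)))
        for _ in range(2):
            pending.append(node.add(Node(length=_blen(scale, rng))))
    for i, leaf in enumerate(pending):
        leaf.name = f"{prefix}{i:03d}"
    return root


def simulate_tree(scenario: SimulationScenario) -> PhyloTree:
    """Rooted synthetic tree with named nodes of interest.

    With ``duplication_at_root`` the root (named ``preLUCA``) joins two
    paralog subtrees whose roots are named ``LUCA_Ffh`` and ``LUCA_FtsY``;
    each paralog subtree splits into a Bacteria and an Archaea clade, and
    leaf names follow the ``gene_domain_phylum_Accession`` convention.
    """
    if scenario.n_taxa_per_clade < 1:
        raise DomainError("need at least 1 taxon per clade")
    rng = np.random.default_rng(scenario.seed)
    build = _birth_death_clade if scenario.tree_shape == "birth_death" else _balanced_clade

    def paralog(gene: str) -> Node:
        node = Node(name=f"LUCA_{gene}", length=_blen(scenario.branch_scale, rng))
        for domain in ("Bacteria", "Archaea"):
            clade = build(scenario.n_taxa_per_clade, scenario.branch_scale,
                          f"{gene}_{domain}_SimPhylum_ACC", rng)
            node.add(clade)
        return node

    if scenario.duplication_at_root:
        root = Node(name="preLUCA", length=0.0)
        root.add(paralog("Ffh"))
        root.add(paralog("FtsY"))
    else:
        root = build(2 * scenario.n_taxa_per_clade, scenario.branch_scale,
                     "Ffh_Bacteria_SimPhylum_ACC", rng)
        root.name = "root"
        root.length = 0.0
    return PhyloTree(root)


def simulate_alignment(tree: PhyloTree, model: RateModel, length: int,
                       root_freqs: Optional[np.ndarray] = None,
                       seed: int = 0) -> tuple[Alignment, str]:
    """Evolve sequences along ``tree`` under ``model``.

    The root sequence is drawn i.i.d. from ``root_freqs`` (default: the
    model's equilibrium frequencies); each child state is sampled from the
    parent state through P(branch length).  Returns the gap-free leaf
    alignment and the true root sequence for recovery tests.
    """
    if length < 1:
        raise DomainError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = model.eq_freqs if root_freqs is None else np.asarray(root_freqs, dtype=float)
    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(20, size=length, p=pi / pi.sum())
    states[id(tree.root)] = root_states
    records = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        cum = np.cumsum(transition_probs(model, node.length), axis=1)
        u = rng.random(length)
        child = np.minimum((u[:, None] > cum[parent_states]).sum(axis=1), 19)
        states[id(node)] = child
        if node.is_leaf:
            records.append((node.name, "".join(AA_ORDER[s] for s in child)))
    # keep a stable, tree-independent record order
    records.sort(key=lambda kv: kv[0])
    root_seq = "".join(AA_ORDER[s] for s in root_states)
    return Alignment(records), root_seq


def overlay_gaps(simulated: Alignment, template: Alignment) -> Alignment:
    """Copy the template's gap coordinates onto the simulated alignment."""
    if simulated.n_columns != template.n_columns:
        raise AlignmentError(
            f"column counts differ: {simulated.n_columns} vs {template.n_columns}")
    if set(simulated.headers) != set(template.headers):
        raise AlignmentError("simulated and template alignments have different taxa")
    out = []
    for header, sim_seq in simulated:
        tmpl = template[header]
        out.append((header, "".join(GAP if tc == GAP else sc
                                    for sc, tc in zip(sim_seq, tmpl))))
    return Alignment(out)


def null_reconstruction_distribution(
        tree: PhyloTree, template_alignment: Alignment, model: RateModel,
        clusters: ClusterSet, node_id: str = "root",
        amino_acids: str = LATE_AMINO_ACIDS, n_sims: int = 100,
        gap_threshold: int = 10, seed: int = 0,
        root_freqs: Optional[np.ndarray] = None,
) -> dict[str, NullDistribution]:
    """Distribution of ancestral amino-acid counts under simulated evolution.

    Each simulation draws tip sequences from the model along ``tree`` (root
    drawn from ``root_freqs``, default the model equilibrium — the WAG null),
    overlays the template's gaps, reduces to one random member per cluster,
    prunes the tree, reconstructs the ancestor at ``node_id`` and calls it at
    ``gap_threshold``; the counts of each requested residue in that single
    reconstruction are recorded.  Per-simulation seeds are ``seed + k`` so
    results do not depend on execution order.  Passing depleted ``root_freqs``
    turns the same machinery into the "observed" arm of a depletion
    experiment.
    """
    if n_sims < 1:
        raise DomainError("n_sims must be >= 1")
    clusters.check_against(template_alignment)
    counts = {aa: np.zeros(n_sims, dtype=int) for aa in amino_acids}
    lengths = np.zeros(n_sims, dtype=int)
    for k in range(n_sims):
        sub_seed = seed + k
        rng = np.random.default_rng(sub_seed)
        sim, _ = simulate_alignment(tree, model, template_alignment.n_columns,
                                    root_freqs=root_freqs, seed=sub_seed)
        gapped = overlay_gaps(sim, template_alignment)
        subset = [c[rng.integers(len(c))] for c in clusters.clusters]
        sub_aln = gapped.subset(subset)
        sub_tree = prune_tree(tree, subset,
                              protected=set() if node_id == "root" else {node_id})
        profile = reconstruct(sub_tree, sub_aln, model, node_id=node_id)
        called = call_sequence(profile, gap_threshold).sequence
        lengths[k] = ungapped_length(called)
        for aa in amino_acids:
            counts[aa][k] = called.count(aa)
    return {aa: NullDistribution(amino_acid=aa, node_id=node_id, counts=c,
                                 root_lengths=lengths.copy())
            for aa, c in counts.items()}
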