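"""Cluster-based dataset reduction and replicate consensus reconstruction.

Large alignments are reduced by sampling one representative per sequence
cluster; ancestral reconstruction is repeated over many such reduced
datasets (the study design uses 100) and the replicate results, which all
live on the master alignment columns, are combined into a simple-majority
consensus per gap threshold.

Cluster membership can come from a file (plain-text dialect with
``Cluster N:`` header lines followed by one member header per line) or be
computed here by a documented greedy single-linkage percent-identity rule
with a soft per-cluster size bound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .asr import AncestralSequence, ReconstructionProfile, call_sequence, reconstruct
from .errors import AlignmentError, DomainError, FormatError, PairingError
from .evomodel import RateModel
from .seqio import AA_ORDER, GAP, MISSING_CODE, Alignment, ReconstructionSet
from .tree import PhyloTree, prune_tree

__all__ = [
    "ClusterSet", "ConsensusSequence", "parse_cluster_file", "cluster_sequences",
    "make_replicates", "prune_tree", "consensus", "replicated_asr",
]

#: Consensus votes in gap-last, then alphabetical order.
_CONSENSUS_ORDER = sorted(AA_ORDER) + [GAP]


@dataclass
class ClusterSet:
    clusters: list[list[str]]
    provenance: str  # "file" | "computed"

    def __post_init__(self):
        if any(not c for c in self.clusters):
            raise FormatError("empty cluster")
        flat = [h for c in self.clusters for h in c]
        if len(flat) != len(set(flat)):
            raise FormatError("clusters are not disjoint")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def members(self) -> set[str]:
        return {h for c in self.clusters for h in c}

    def check_against(self, alignment: Alignment) -> None:
        missing = sorted(self.members - set(alignment.headers))
        if missing:
            raise PairingError(f"cluster members absent from alignment: {missing[:5]}")


@dataclass
class ConsensusSequence:
    node_id: str
    gap_threshold: int
    sequence: str
    winning_frequency: np.ndarray  # per column, fraction of votes for the winner


_CLUSTER_RE = re.compile(r"^\s*Cluster\s+(\S+)\s*:?\s*$", re.IGNORECASE)


def parse_cluster_file(path: str | Path, strict: bool = False) -> ClusterSet:
    """Parse the plain-text cluster dialect.

    Grammar (tolerant mode): lines matching ``Cluster <id>:`` open a new
    cluster; every following non-blank line contributes one member header
    (a leading ``>`` and any surrounding whitespace are stripped).  In strict
    mode, any non-blank line before the first cluster header is an error;
    tolerant mode skips such preamble lines.
    """
    clusters: list[list[str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if _CLUSTER_RE.match(line):
            clusters.append([])
            continue
        if not clusters:
            if strict:
                raise FormatError(f"{path}:{lineno}: member line before any 'Cluster N:' header")
            continue
        clusters[-1].append(line.lstrip(">").strip())
    if not clusters:
        raise FormatError(f"{path}: no clusters found")
    return ClusterSet(clusters=[c for c in clusters if c], provenance="file")


def write_cluster_file(path: str | Path, clusters: ClusterSet) -> None:
    with open(path, "w") as fh:
        for i, members in enumerate(clusters.clusters, 1):
            fh.write(f"Cluster {i}:\n")
            for m in members:
                fh.write(f"{m}\n")


def _pairwise_pid(enc: np.ndarray, i: int, j: int) -> float:
    """Percent identity between encoded rows; denominator = columns where
    at least one member holds a residue."""
    a, b = enc[i], enc[j]
    either = (a != MISSING_CODE) | (b != MISSING_CODE)
    denom = int(either.sum())
    if denom == 0:
        return 0.0
    same = int(((a == b) & (a != MISSING_CODE)).sum())
    return 100.0 * same / denom


def cluster_sequences(alignment: Alignment, soft_max: int, seed: int,
                      min_identity: float = 20.0) -> ClusterSet:
    """Greedy single-linkage percent-identity clustering with a soft size bound.

    Sequences are visited in an order randomised by ``seed``.  Each sequence
    joins the cluster containing its nearest neighbour, provided that
    neighbour is at least ``min_identity`` percent identical; when the best
    cluster is full (``soft_max`` members) the sequence falls back to another
    cluster within 5 identity points of the best, else it starts a new
    cluster.  Sequences with no neighbour above ``min_identity`` become
    singletons.
    """
    if soft_max < 1:
        raise DomainError("soft_max must be >= 1")
    rng = np.random.default_rng(seed)
    enc = alignment.encoded()
    headers = alignment.headers
    order = rng.permutation(len(headers))

    clusters: list[list[int]] = []
    for i in order:
        if not clusters:
            clusters.append([int(i)])
            continue
        # best (max) single-linkage identity to each cluster
        best = [max(_pairwise_pid(enc, int(i), m) for m in c) for c in clusters]
        ranked = sorted(range(len(clusters)), key=lambda k: -best[k])
        target = None
        top = ranked[0]
        if best[top] >= min_identity:
            if len(clusters[top]) < soft_max:
                target = top
            else:
                for k in ranked[1:]:
                    if best[top] - best[k] <= 5.0 and len(clusters[k]) < soft_max:
                        target = k
                        break
        if target is None:
            clusters.append([int(i)])
        else:
            clusters[target].append(int(i))
    return ClusterSet(clusters=[[headers[m] for m in c] for c in clusters],
                      provenance="computed")


def make_replicates(clusters: ClusterSet, n: int, seed: int) -> list[list[str]]:
    """n header subsets, one randomly chosen member per cluster.

    Replicate ``r`` draws from an independent stream seeded ``seed + r`` so
    results are reproducible and independent of execution order.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    subsets = []
    for r in range(n):
        rng = np.random.default_rng(seed + r)
        subsets.append([c[rng.integers(len(c))] for c in clusters.clusters])
    return subsets


def consensus(sequences: Sequence[str], node_id: str = "",
              gap_threshold: int = 50) -> ConsensusSequence:
    """Simple-majority per-column consensus over {20 residues, '-'}.

    Ties break in favour of residues over the gap, then alphabetically.
    """
    if not sequences:
        raise DomainError("consensus requires at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise AlignmentError(f"consensus input lengths differ: {sorted(lengths)}")
    n_cols = lengths.pop()
    mat = np.array([list(s) for s in sequences])
    chars = []
    winfreq = np.empty(n_cols)
    for c in range(n_cols):
        col = mat[:, c]
        # vote in tie-break order so the first max wins
        counts = [(sym, int((col == sym).sum())) for sym in _CONSENSUS_ORDER]
        sym, cnt = max(counts, key=lambda kv: kv[1])
        chars.append(sym)
        winfreq[c] = cnt / len(sequences)
    return ConsensusSequence(node_id=node_id, gap_threshold=gap_threshold,
                             sequence="".join(chars), winning_frequency=winfreq)


def replicated_asr(alignment: Alignment, tree: PhyloTree, model: RateModel,
                   clusters: ClusterSet, node_id: str = "root",
                   thresholds: Sequence[int] = (10, 50, 90),
                   n: int = 100, seed: int = 0,
                   ) -> tuple[dict[int, ReconstructionSet], dict[int, ConsensusSequence]]:
    """Replicate-resampled ASR with per-threshold consensus.

    For each replicate: sample one member per cluster, subset the master
    alignment rows (columns preserved), prune the guide tree to the subset,
    compute residue and gap posteriors at ``node_id``, and call a sequence at
    each gap threshold.  Replicate sequences share the master columns, so a
    per-threshold simple-majority consensus is well defined.
    """
    clusters.check_against(alignment)
    subsets = make_replicates(clusters, n, seed)
    sets = {t: ReconstructionSet(node_id=node_id, gap_threshold=t, sequences=[])
            for t in thresholds}
    protected = set() if node_id == "root" else {node_id}
    for subset in subsets:
        sub_aln = alignment.subset(subset)
        sub_tree = prune_tree(tree, subset, protected=protected)
        profile = reconstruct(sub_tree, sub_aln, model, node_id=node_id)
        for t in thresholds:
            sets[t].sequences.append(call_sequence(profile, t).sequence)
    cons = {t: consensus(sets[t].sequences, node_id=node_id, gap_threshold=t)
            for t in thresholds}
    return sets, cons
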