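"""Marginal ancestral sequence reconstruction with ML gap inference.

The residue part is standard Felsenstein pruning over the 20 amino-acid
states: gaps and X in the alignment are missing data (partial likelihood 1
for every state), and the marginal posterior at an internal node is obtained
with the up-down (outside) algorithm, so one pass serves every node.

The gap/residue decision is made by a separate binary-character analysis:
each column is recoded presence(1)/absence(0) and reconstructed under a
2-state reversible model with equal stationary frequencies and a single
indel rate.  The rate is estimated by maximising the binary likelihood over
log-rate in [-5, 2] (natural log).  An ancestral column is called a gap when
its posterior probability of absence reaches the chosen threshold; raising
the threshold therefore monotonically lengthens the called sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError, PairingError
from .evomodel import N_STATES, RateModel, transition_probs
from .seqio import AA_ORDER, GAP, MISSING_CODE, Alignment
from .tree import Node, PhyloTree

__all__ = [
    "ReconstructionProfile", "AncestralSequence",
    "site_log_likelihood", "marginal_posteriors", "gap_posteriors",
    "estimate_indel_rate", "reconstruct", "call_sequence", "threshold_sweep",
]

# Alphabetical tie-break order for argmax residue calls.
_ALPHA_RANK = np.array([sorted(AA_ORDER).index(a) for a in AA_ORDER])


@dataclass
class ReconstructionProfile:
    """Per-column ancestral posteriors at one internal node."""

    node_id: str
    residue_posterior: np.ndarray          # (n_columns, 20), rows sum to 1
    gap_posterior: Optional[np.ndarray] = None   # (n_columns,) in [0, 1]
    indel_rate: Optional[float] = None

    @property
    def n_columns(self) -> int:
        return self.residue_posterior.shape[0]


@dataclass(frozen=True)
class AncestralSequence:
    node_id: str
    gap_threshold: int
    sequence: str


def _check_pairing(tree: PhyloTree, alignment: Alignment) -> None:
    leaf_set = set(tree.leaf_names())
    aln_set = set(alignment.headers)
    if leaf_set != aln_set:
        only_tree = sorted(leaf_set - aln_set)[:5]
        only_aln = sorted(aln_set - leaf_set)[:5]
        raise PairingError(
            f"tree/alignment name mismatch; tree-only: {only_tree}, alignment-only: {only_aln}")


def _leaf_partials(codes: np.ndarray, n_states: int) -> np.ndarray:
    """(n_cols, n_states) partial likelihoods for one encoded leaf row."""
    n_cols = codes.shape[0]
    part = np.zeros((n_cols, n_states))
    observed = codes < n_states
    part[observed, codes[observed]] = 1.0
    part[~observed, :] = 1.0  # gap / X: missing data
    return part


class _Pruning:
    """Up (postorder) and down (outside) passes over one tree.

    Partial likelihoods are rescaled per column; log scale factors are
    carried separately so site likelihoods do not underflow on deep trees.
    """

    def __init__(self, tree: PhyloTree, leaf_codes: dict[str, np.ndarray],
                 n_states: int, trans, prior: np.ndarray):
        self.tree = tree
        self.n_states = n_states
        self.prior = prior
        self.nodes = list(tree.postorder())
        self.idx = {id(n): i for i, n in enumerate(self.nodes)}
        n_cols = next(iter(leaf_codes.values())).shape[0]
        self.n_cols = n_cols

        # Up pass.
        self.L = [None] * len(self.nodes)        # partials at node
        self.Lscale = [None] * len(self.nodes)   # per-column log scale
        self.M = [None] * len(self.nodes)        # child message through its branch
        self.P = [None] * len(self.nodes)        # transition matrix on branch above node
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                self.L[i] = _leaf_partials(leaf_codes[node.name], n_states)
                self.Lscale[i] = np.zeros(n_cols)
            else:
                part = np.ones((n_cols, n_states))
                scale = np.zeros(n_cols)
                for child in node.children:
                    j = self.idx[id(child)]
                    part = part * self.M[j]
                    scale = scale + self.Lscale[j]
                m = part.max(axis=1)
                m[m == 0] = 1.0
                part /= m[:, None]
                self.L[i] = part
                self.Lscale[i] = scale + np.log(m)
            if node is not tree.root:
                p = trans(node.length)
                self.P[i] = p
                msg = self.L[i] @ p.T
                self.M[i] = msg
        # message scales equal partial scales (messages are not rescaled again)
        self.Mscale = self.Lscale

    def site_log_likelihood(self) -> np.ndarray:
        i = self.idx[id(self.tree.root)]
        like = self.L[i] @ self.prior
        return np.log(like) + self.Lscale[i]

    def outside(self) -> tuple[list, list]:
        """U[i](x): likelihood of data outside node i's subtree given state x."""
        U = [None] * len(self.nodes)
        Uscale = [None] * len(self.nodes)
        ri = self.idx[id(self.tree.root)]
        U[ri] = np.broadcast_to(self.prior, (self.n_cols, self.n_states)).copy()
        Uscale[ri] = np.zeros(self.n_cols)
        for node in self.tree.preorder():
            i = self.idx[id(node)]
            for child in node.children:
                j = self.idx[id(child)]
                w = U[i].copy()
                wscale = Uscale[i].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    k = self.idx[id(sib)]
                    w = w * self.M[k]
                    wscale = wscale + self.Mscale[k]
                u = w @ self.P[j]
                m = u.max(axis=1)
                m[m == 0] = 1.0
                u /= m[:, None]
                U[j] = u
                Uscale[j] = wscale + np.log(m)
        return U, Uscale

    def posterior_at(self, node: Node) -> np.ndarray:
        U, _ = self.outside()
        i = self.idx[id(node)]
        post = self.L[i] * U[i]
        total = post.sum(axis=1, keepdims=True)
        return post / total


def _residue_pruning(tree: PhyloTree, alignment: Alignment, model: RateModel,
                     category_rate: float = 1.0) -> _Pruning:
    _check_pairing(tree, alignment)
    enc = alignment.encoded()
    codes = {h: enc[i] for i, h in enumerate(alignment.headers)}
    return _Pruning(tree, codes, N_STATES,
                    trans=lambda t: transition_probs(model, t, category_rate),
                    prior=model.eq_freqs)


def site_log_likelihood(tree: PhyloTree, alignment: Alignment, model: RateModel) -> np.ndarray:
    """Per-column log-likelihood under the model, root weighted by eq_freqs.

    With >1 rate category, the site likelihood is the equal-weight mixture
    over category-scaled branch lengths.
    """
    rates = model.category_rates
    per_cat = np.stack([
        _residue_pruning(tree, alignment, model, r).site_log_likelihood() for r in rates
    ])
    if len(rates) == 1:
        return per_cat[0]
    mx = per_cat.max(axis=0)
    return mx + np.log(np.mean(np.exp(per_cat - mx), axis=0))


def marginal_posteriors(tree: PhyloTree, alignment: Alignment, model: RateModel,
                        node_id: str = "root") -> ReconstructionProfile:
    """Marginal per-column posterior over the 20 states at one internal node."""
    node = tree.root if node_id == "root" else tree.find(node_id)
    if node.is_leaf:
        raise DomainError(f"node {node_id!r} is a leaf; marginal ASR targets internal nodes")
    rates = model.category_rates
    if len(rates) == 1:
        post = _residue_pruning(tree, alignment, model).posterior_at(node)
    else:
        # Mixture posterior: weight category posteriors by category site likelihood.
        posts, logls = [], []
        for r in rates:
            eng = _residue_pruning(tree, alignment, model, r)
            posts.append(eng.posterior_at(node))
            logls.append(eng.site_log_likelihood())
        logls = np.stack(logls)
        w = np.exp(logls - logls.max(axis=0))
        w /= w.sum(axis=0)
        post = np.einsum("kc,kcs->cs", w, np.stack(posts))
    name = node_id if node_id != "root" else (node.name or "root")
    return ReconstructionProfile(node_id=name, residue_posterior=post)


# -- binary presence/absence model -----------------------------------------

def _binary_trans(rate: float):
    def p(t: float) -> np.ndarray:
        e = math.exp(-2.0 * rate * t)
        same = 0.5 * (1.0 + e)
        diff = 0.5 * (1.0 - e)
        return np.array([[same, diff], [diff, same]])
    return p


def _presence_codes(alignment: Alignment) -> dict[str, np.ndarray]:
    enc = alignment.encoded()
    # state 1 = residue or X present, state 0 = gap
    pres = (enc != MISSING_CODE).astype(np.int8)
    xmask = np.array([[c == "X" for c in seq] for seq in alignment.sequences])
    pres[xmask] = 1
    return {h: pres[i] for i, h in enumerate(alignment.headers)}


def _binary_pruning(tree: PhyloTree, alignment: Alignment, rate: float) -> _Pruning:
    _check_pairing(tree, alignment)
    return _Pruning(tree, _presence_codes(alignment), 2,
                    trans=_binary_trans(rate), prior=np.array([0.5, 0.5]))


def estimate_indel_rate(tree: PhyloTree, alignment: Alignment,
                        log_rate_bounds: tuple[float, float] = (-5.0, 2.0),
                        tol: float = 1e-4) -> float:
    """ML single indel rate for the binary presence/absence characters."""
    def neg_loglik(log_rate: float) -> float:
        eng = _binary_pruning(tree, alignment, math.exp(log_rate))
        return -float(eng.site_log_likelihood().sum())

    res = minimize_scalar(neg_loglik, bounds=log_rate_bounds, method="bounded",
                          options={"xatol": tol})
    return math.exp(res.x)


def gap_posteriors(tree: PhyloTree, alignment: Alignment,
                   indel_rate: Optional[float] = None,
                   node_id: str = "root") -> tuple[np.ndarray, float]:
    """Posterior probability of the gap (absence) state per column at a node.

    When ``indel_rate`` is None it is first estimated by ML.  Returns the
    per-column gap probability and the rate that was used.
    """
    node = tree.root if node_id == "root" else tree.find(node_id)
    if node.is_leaf:
        raise DomainError(f"node {node_id!r} is a leaf")
    if indel_rate is None:
        indel_rate = estimate_indel_rate(tree, alignment)
    if indel_rate <= 0:
        raise DomainError("indel_rate must be positive")
    post = _binary_pruning(tree, alignment, indel_rate).posterior_at(node)
    return post[:, 0], indel_rate


def reconstruct(tree: PhyloTree, alignment: Alignment, model: RateModel,
                node_id: str = "root", indel_rate: Optional[float] = None) -> ReconstructionProfile:
    """Full profile at one node: residue posteriors plus gap posteriors."""
    prof = marginal_posteriors(tree, alignment, model, node_id)
    gp, rate = gap_posteriors(tree, alignment, indel_rate, node_id)
    prof.gap_posterior = gp
    prof.indel_rate = rate
    return prof


def call_sequence(profile: ReconstructionProfile, gap_threshold: int) -> AncestralSequence:
    """Threshold the profile into a gapped sequence on master columns.

    A column is a gap iff its gap posterior >= threshold/100, otherwise the
    maximum-posterior residue; posterior ties break alphabetically.
    """
    if not 1 <= gap_threshold <= 99:
        raise DomainError(f"gap_threshold {gap_threshold} outside [1, 99]")
    if profile.gap_posterior is None:
        raise DomainError("profile has no gap posteriors; run gap_posteriors first")
    post = profile.residue_posterior
    # argmax with alphabetical tie-break: lexicographic on (-posterior, letter rank)
    order = np.lexsort((_ALPHA_RANK[None, :].repeat(post.shape[0], 0), -post), axis=1)
    best = order[:, 0]
    chars = np.array(list(AA_ORDER))[best]
    is_gap = profile.gap_posterior >= gap_threshold / 100.0
    seq = "".join(GAP if g else c for g, c in zip(is_gap, chars))
    return AncestralSequence(node_id=profile.node_id, gap_threshold=gap_threshold, sequence=seq)


def threshold_sweep(profile: ReconstructionProfile,
                    thresholds: Sequence[int] = range(1, 100)) -> np.ndarray:
    """Per-column fraction of thresholds at which a residue (not gap) is called."""
    if profile.gap_posterior is None:
        raise DomainError("profile has no gap posteriors")
    thr = np.asarray(list(thresholds), dtype=float) / 100.0
    gp = profile.gap_posterior[:, None]
    residue_called = gp < thr[None, :]
    return residue_called.mean(axis=1)
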