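"""Pruning-kernel correctness against naive enumeration, posterior
properties, threshold semantics."""

import math
from itertools import product

import numpy as np
import pytest

from conftest import make_alignment
from srpasr.asr import (ReconstructionProfile, call_sequence, estimate_indel_rate,
                        gap_posteriors, marginal_posteriors, reconstruct,
                        site_log_likelihood, threshold_sweep)
from srpasr.errors import DomainError, PairingError
from srpasr.evomodel import transition_probs
from srpasr.seqio import AA_INDEX, AA_ORDER, Alignment, ungapped_length
from srpasr.simulate import simulate_alignment, simulate_tree, SimulationScenario
from srpasr.tree import PhyloTree


# -- independent oracle: enumerate all internal-node state assignments -------

def naive_likelihood_and_posterior(tree, alignment, model, col, target):
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    P = {id(n): transition_probs(model, n.length) for n in nodes}
    chars = {n.name: alignment[n.name][col] for n in tree.leaves()}
    total, post = 0.0, np.zeros(20)
    for assign in product(range(20), repeat=len(internals)):
        state = dict(zip((id(n) for n in internals), assign))
        p = model.eq_freqs[state[id(tree.root)]]
        for n in nodes:
            if n is tree.root:
                continue
            parent_state = state[id(n.parent)]
            if n.is_leaf:
                ch = chars[n.name]
                p *= 1.0 if ch in "-X" else P[id(n)][parent_state, AA_INDEX[ch]]
            else:
                p *= P[id(n)][parent_state, state[id(n)]]
        total += p
        post[state[id(target)]] += p
    return total, post / total


def naive_binary(tree, alignment, rate, col, target):
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]

    def ptrans(t):
        e = math.exp(-2 * rate * t)
        return np.array([[0.5 * (1 + e), 0.5 * (1 - e)], [0.5 * (1 - e), 0.5 * (1 + e)]])

    P = {id(n): ptrans(n.length) for n in nodes}
    obs = {n.name: 0 if alignment[n.name][col] == "-" else 1 for n in tree.leaves()}
    total, post = 0.0, np.zeros(2)
    for assign in product(range(2), repeat=len(internals)):
        state = dict(zip((id(n) for n in internals), assign))
        p = 0.5
        for n in nodes:
            if n is tree.root:
                continue
            parent_state = state[id(n.parent)]
            tgt = obs[n.name] if n.is_leaf else state[id(n)]
            p *= P[id(n)][parent_state, tgt]
        total += p
        post[state[id(target)]] += p
    return post / total


NAMES4 = ["Ffh_Bacteria_P_a", "Ffh_Bacteria_P_b", "Ffh_Archaea_P_c", "Ffh_Archaea_P_d"]
TREE4 = ("((Ffh_Bacteria_P_a:0.12,Ffh_Bacteria_P_b:0.3):0.25,"
         "(Ffh_Archaea_P_c:0.4,Ffh_Archaea_P_d:0.07):0.18);")


class TestSiteLikelihood:
    def test_star_tree_enumeration(self, star3, wag):
        aln = make_alignment(star3, ["AAV"])
        ll = site_log_likelihood(star3, aln, wag)
        p = transition_probs(wag, 0.1)
        brute = math.log(sum(wag.eq_freqs[x] * p[x, AA_INDEX["A"]] ** 2
                             * p[x, AA_INDEX["V"]] for x in range(20)))
        assert ll[0] == pytest.approx(brute, abs=1e-12)

    def test_single_informative_leaf_closed_form(self, wag):
        # with one observed leaf the column likelihood is just pi[state]
        tree = PhyloTree.from_newick("(Ffh_Bacteria_P_a:0.5,Ffh_Bacteria_P_b:1.3);")
        aln = Alignment([("Ffh_Bacteria_P_a", "A"), ("Ffh_Bacteria_P_b", "-")])
        ll = site_log_likelihood(tree, aln, wag)
        assert ll[0] == pytest.approx(math.log(wag.eq_freqs[AA_INDEX["A"]]), abs=1e-12)

    def test_all_gap_column_likelihood_one(self, star3, wag):
        aln = make_alignment(star3, ["AAA", "---"])
        ll = site_log_likelihood(star3, aln, wag)
        assert ll[1] == pytest.approx(0.0, abs=1e-12)

    def test_four_taxon_enumeration(self, wag):
        tree = PhyloTree.from_newick(TREE4)
        aln = Alignment(list(zip(NAMES4, ["MK", "MR", "LK", "-W"])))
        ll = site_log_likelihood(tree, aln, wag)
        for col in range(2):
            total, _ = naive_likelihood_and_posterior(tree, aln, wag, col, tree.root)
            assert ll[col] == pytest.approx(math.log(total), abs=1e-10)

    def test_name_mismatch_lists_offenders(self, star3, wag):
        aln = Alignment([("Ffh_Bacteria_P_a1", "A"), ("Ffh_Bacteria_P_zz", "A")])
        with pytest.raises(PairingError, match="zz"):
            site_log_likelihood(star3, aln, wag)


class TestMarginalPosteriors:
    def test_zero_branch_limit(self, wag):
        tree = PhyloTree.from_newick("(Ffh_Bacteria_P_a:1e-8,Ffh_Bacteria_P_b:1e-8);")
        aln = Alignment([("Ffh_Bacteria_P_a", "A"), ("Ffh_Bacteria_P_b", "A")])
        prof = marginal_posteriors(tree, aln, wag, "root")
        assert prof.residue_posterior[0, AA_INDEX["A"]] > 0.999

    def test_star_tree_matches_enumeration(self, star3, wag):
        aln = make_alignment(star3, ["AAV"])
        prof = marginal_posteriors(star3, aln, wag, "root")
        p = transition_probs(wag, 0.1)
        brute = np.array([wag.eq_freqs[x] * p[x, AA_INDEX["A"]] ** 2 * p[x, AA_INDEX["V"]]
                          for x in range(20)])
        brute /= brute.sum()
        assert np.abs(prof.residue_posterior[0] - brute).max() < 1e-10

    def test_internal_node_matches_enumeration(self, wag):
        tree = PhyloTree.from_newick(TREE4)
        aln = Alignment(list(zip(NAMES4, ["MKW", "MRX", "LK-", "GWA"])))
        internal = [n for n in tree.postorder() if not n.is_leaf and n is not tree.root][0]
        internal.name = "probe"
        prof = marginal_posteriors(tree, aln, wag, "probe")
        for col in range(3):
            _, post = naive_likelihood_and_posterior(tree, aln, wag, col, internal)
            assert np.abs(prof.residue_posterior[col] - post).max() < 1e-10

    def test_rows_sum_to_one(self, wag, duplication_bundle):
        tree, aln, _ = duplication_bundle
        prof = marginal_posteriors(tree, aln, wag, "root")
        assert np.abs(prof.residue_posterior.sum(axis=1) - 1).max() < 1e-8

    def test_pulley_principle(self, wag):
        """For a reversible model, sliding the root along the central branch
        changes neither the likelihood nor the posterior at a fixed internal
        node (the root itself is a different tree point, so it is excluded)."""
        a = PhyloTree.from_newick("((Ffh_Bacteria_P_a:0.1,Ffh_Bacteria_P_b:0.2)probe:0.15,"
                                  "(Ffh_Archaea_P_c:0.3,Ffh_Archaea_P_d:0.25):0.05);")
        b = PhyloTree.from_newick("((Ffh_Bacteria_P_a:0.1,Ffh_Bacteria_P_b:0.2)probe:0.05,"
                                  "(Ffh_Archaea_P_c:0.3,Ffh_Archaea_P_d:0.25):0.15);")
        aln = Alignment(list(zip(NAMES4, ["MW", "MK", "LW", "AW"])))
        lla = site_log_likelihood(a, aln, wag)
        llb = site_log_likelihood(b, aln, wag)
        assert np.abs(lla - llb).max() < 1e-10
        pa = marginal_posteriors(a, aln, wag, "probe").residue_posterior
        pb = marginal_posteriors(b, aln, wag, "probe").residue_posterior
        assert np.abs(pa - pb).max() < 1e-10

    def test_leaf_target_rejected(self, star3, wag):
        aln = make_alignment(star3, ["AAA"])
        with pytest.raises(DomainError):
            marginal_posteriors(star3, aln, wag, "Ffh_Bacteria_P_a1")


class TestGapPosteriors:
    def test_unanimous_absence(self, wag):
        tree = PhyloTree.from_newick("(Ffh_Bacteria_P_a:0.01,Ffh_Bacteria_P_b:0.01);")
        aln = Alignment([("Ffh_Bacteria_P_a", "-A"), ("Ffh_Bacteria_P_b", "-A")])
        gp, _ = gap_posteriors(tree, aln, 1.0, "root")
        assert gp[0] > 0.99 and gp[1] < 0.01

    def test_binary_enumeration_oracle(self, wag):
        tree = PhyloTree.from_newick(
            "(Ffh_Bacteria_P_a1:0.2,Ffh_Bacteria_P_a2:0.2,Ffh_Bacteria_P_a3:0.2);")
        aln = Alignment([("Ffh_Bacteria_P_a1", "A"), ("Ffh_Bacteria_P_a2", "A"),
                         ("Ffh_Bacteria_P_a3", "-")])
        gp, _ = gap_posteriors(tree, aln, 1.0, "root")
        brute = naive_binary(tree, aln, 1.0, 0, tree.root)
        assert gp[0] == pytest.approx(brute[0], abs=1e-10)

    def test_four_taxon_enumeration(self, wag):
        tree = PhyloTree.from_newick(TREE4)
        aln = Alignment(list(zip(NAMES4, ["A-", "AA", "--", "A-"])))
        gp, _ = gap_posteriors(tree, aln, 0.7, "root")
        for col in range(2):
            brute = naive_binary(tree, aln, 0.7, col, tree.root)
            assert gp[col] == pytest.approx(brute[0], abs=1e-10)

    def test_rate_estimation_is_positive_and_deterministic(self, duplication_bundle):
        tree, aln, _ = duplication_bundle
        r1 = estimate_indel_rate(tree, aln)
        r2 = estimate_indel_rate(tree, aln)
        assert r1 == r2 > 0


def make_profile(gap_posts, residue_hot=None):
    n = len(gap_posts)
    post = np.full((n, 20), 1.0 / 20)
    if residue_hot:
        for c, aa in enumerate(residue_hot):
            post[c] = 0.0
            post[c, AA_INDEX[aa]] = 1.0
    return ReconstructionProfile(node_id="root", residue_posterior=post,
                                 gap_posterior=np.asarray(gap_posts, dtype=float))


class TestCallSequence:
    def test_threshold_semantics(self):
        prof = make_profile([0.95, 0.5], residue_hot="KK")
        assert call_sequence(prof, 90).sequence == "-K"
        assert call_sequence(prof, 96).sequence == "KK"

    def test_exact_threshold_is_gap(self):
        prof = make_profile([0.90], residue_hot="K")
        assert call_sequence(prof, 90).sequence == "-"

    def test_tie_breaks_alphabetically(self):
        # N precedes D in the model's residue ordering but D < N alphabetically
        post = np.zeros((1, 20))
        post[0, AA_INDEX["N"]] = 0.5
        post[0, AA_INDEX["D"]] = 0.5
        prof = ReconstructionProfile("root", post, np.array([0.0]))
        assert call_sequence(prof, 50).sequence == "D"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        prof = make_profile(rng.random(80))
        lengths = [ungapped_length(call_sequence(prof, t).sequence)
                   for t in (10, 50, 90)]
        assert lengths == sorted(lengths)

    def test_threshold_bounds(self):
        with pytest.raises(DomainError):
            call_sequence(make_profile([0.5]), 0)


class TestThresholdSweep:
    @pytest.mark.parametrize("gp,expected", [
        (0.0, 1.0),
        (1.0, 0.0),
        (0.5, 49 / 99),   # thresholds 51..99 call a residue
    ])
    def test_occupancy(self, gp, expected):
        occ = threshold_sweep(make_profile([gp]))
        assert occ[0] == pytest.approx(expected)

    def test_matches_explicit_enumeration(self):
        rng = np.random.default_rng(1)
        gps = rng.random(20)
        occ = threshold_sweep(make_profile(gps))
        for c, gp in enumerate(gps):
            manual = sum(gp < t / 100 for t in range(1, 100)) / 99
            assert occ[c] == pytest.approx(manual)


class TestRootRecovery:
    def test_beats_leaf_majority_baseline(self, wag):
        """On shallow simulated trees the called root at 50% gap threshold is
        at least as accurate as the per-column majority of leaf residues."""
        accs_asr, accs_maj = [], []
        for rep in range(6):
            scen = SimulationScenario(n_taxa_per_clade=8, branch_scale=0.05,
                                      length=300, seed=100 + rep)
            tree = simulate_tree(scen)
            aln, true_root = simulate_alignment(tree, wag, 300, seed=100 + rep)
            prof = reconstruct(tree, aln, wag, node_id="root")
            called = call_sequence(prof, 50).sequence
            accs_asr.append(np.mean([a == b for a, b in zip(called, true_root)]))
            enc = aln.encoded()
            maj = [np.bincount(enc[:, c], minlength=21)[:20].argmax()
                   for c in range(aln.n_columns)]
            maj_seq = "".join(AA_ORDER[i] for i in maj)
            accs_maj.append(np.mean([a == b for a, b in zip(maj_seq, true_root)]))
        assert np.mean(accs_asr) >= np.mean(accs_maj) - 1e-12
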