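import numpy as np
import pytest

from srpasr.asr import call_sequence, reconstruct
from srpasr.errors import AlignmentError, DomainError, FormatError, PruneError
from srpasr.resample import (ClusterSet, cluster_sequences, consensus,
                             make_replicates, parse_cluster_file, replicated_asr,
                             write_cluster_file)
from srpasr.seqio import AA_ORDER, Alignment, ungapped_length
from srpasr.tree import PhyloTree, prune_tree

CLUSTER_TEXT = """\
Cluster 1:
FtsY_Bacteria_P_a1
FtsY_Bacteria_P_a2
Cluster 2:
Ffh_Archaea_T_b1
"""


class TestClusterFile:
    def test_parse_dialect(self, tmp_path):
        p = tmp_path / "clusters.txt"
        p.write_text(CLUSTER_TEXT)
        cs = parse_cluster_file(p)
        assert len(cs) == 2
        assert cs.clusters[0] == ["FtsY_Bacteria_P_a1", "FtsY_Bacteria_P_a2"]
        assert cs.provenance == "file"

    def test_tolerant_skips_preamble_strict_rejects(self, tmp_path):
        p = tmp_path / "clusters.txt"
        p.write_text("some header line\n" + CLUSTER_TEXT)
        assert len(parse_cluster_file(p)) == 2
        with pytest.raises(FormatError):
            parse_cluster_file(p, strict=True)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(FormatError):
            parse_cluster_file(p)

    def test_round_trip(self, tmp_path):
        cs = ClusterSet(clusters=[["a", "b"], ["c"]], provenance="computed")
        p = tmp_path / "out.txt"
        write_cluster_file(p, cs)
        assert [c for c in parse_cluster_file(p).clusters] == cs.clusters

    def test_member_missing_from_alignment(self, tmp_path):
        p = tmp_path / "clusters.txt"
        p.write_text(CLUSTER_TEXT)
        cs = parse_cluster_file(p)
        aln = Alignment([("FtsY_Bacteria_P_a1", "A"), ("FtsY_Bacteria_P_a2", "A")])
        with pytest.raises(Exception, match="Ffh_Archaea_T_b1"):
            cs.check_against(aln)


class TestClusterSequences:
    def test_identical_sequences_split_by_soft_max(self):
        aln = Alignment([(f"Ffh_Bacteria_P_x{i}", "MKLV" * 5) for i in range(10)])
        cs = cluster_sequences(aln, soft_max=5, seed=0)
        assert sorted(len(c) for c in cs.clusters) == [5, 5]

    def test_dissimilar_sequences_stay_singletons(self):
        # pairwise identity 0% between any two records
        aln = Alignment([(f"Ffh_Bacteria_P_x{i}", AA_ORDER[i] * 12) for i in range(10)])
        cs = cluster_sequences(aln, soft_max=5, seed=3)
        assert len(cs) == 10

    def test_deterministic_under_seed(self):
        aln = Alignment([(f"Ffh_Bacteria_P_x{i}", ("MKLV" if i < 5 else "MWDE") * 4)
                         for i in range(10)])
        a = cluster_sequences(aln, soft_max=5, seed=9)
        b = cluster_sequences(aln, soft_max=5, seed=9)
        assert a.clusters == b.clusters
        assert a.members == set(aln.headers)


class TestMakeReplicates:
    def test_one_member_per_cluster(self):
        cs = ClusterSet(clusters=[["a", "b"], ["c", "d"], ["e"]], provenance="file")
        subsets = make_replicates(cs, n=7, seed=1)
        assert len(subsets) == 7
        for s in subsets:
            assert len(s) == 3
            assert s[0] in ("a", "b") and s[1] in ("c", "d") and s[2] == "e"

    def test_singleton_clusters_give_identical_subsets(self):
        cs = ClusterSet(clusters=[["a"], ["b"]], provenance="file")
        subsets = make_replicates(cs, n=4, seed=0)
        assert all(s == ["a", "b"] for s in subsets)

    def test_seeded_determinism(self):
        cs = ClusterSet(clusters=[["a", "b", "c"], ["d", "e"]], provenance="file")
        assert make_replicates(cs, 5, seed=2) == make_replicates(cs, 5, seed=2)


class TestPruneTree:
    def test_keep_all_is_identity(self):
        t = PhyloTree.from_newick("((a:1,b:1):1,c:2);")
        pruned = prune_tree(t, {"a", "b", "c"})
        assert sorted(pruned.leaf_names()) == ["a", "b", "c"]
        assert pruned.to_newick() == t.to_newick()

    def test_path_compression_sums_branches(self):
        t = PhyloTree.from_newick("((a:1,b:1):1,c:2);")
        pruned = prune_tree(t, {"a", "c"})
        lengths = {n.name: n.length for n in pruned.leaves()}
        assert lengths == {"a": 2.0, "c": 2.0}

    def test_leaf_set_equals_keep(self):
        t = PhyloTree.from_newick("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):2);")
        pruned = prune_tree(t, {"a", "d", "f"})
        assert sorted(pruned.leaf_names()) == ["a", "d", "f"]

    def test_named_node_losing_one_side_errors(self):
        t = PhyloTree.from_newick("((a:1,b:1)LUCA_Ffh:1,(c:1,d:1)LUCA_FtsY:1);")
        with pytest.raises(PruneError, match="LUCA_Ffh"):
            prune_tree(t, {"a", "c", "d"})

    def test_named_node_survives_with_both_sides(self):
        t = PhyloTree.from_newick("(((a:1,b:1):1,(c:1,d:1):1)LUCA_Ffh:1,(e:1,f:1):2);")
        pruned = prune_tree(t, {"a", "c", "e", "f"})
        assert pruned.find("LUCA_Ffh") is not None


class TestConsensus:
    @pytest.mark.parametrize("column,expected", [
        (["A", "A", "G"], "A"),
        (["A", "A", "G", "G"], "A"),    # alphabetical tie-break
        (["A", "-", "-"], "-"),
        (["A", "A", "-", "-"], "A"),    # residue beats gap on ties
    ])
    def test_column_rules(self, column, expected):
        assert consensus(column).sequence == expected

    def test_identity_on_identical_inputs(self):
        cons = consensus(["MK-W"] * 5)
        assert cons.sequence == "MK-W"
        assert np.all(cons.winning_frequency == 1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            consensus(["A", "CD"])

    def test_winning_frequency(self):
        cons = consensus(["AA", "AG", "GG"])
        assert cons.winning_frequency[0] == pytest.approx(2 / 3)


class TestReplicatedAsr:
    def test_single_replicate_singletons_equals_direct(self, wag, duplication_bundle):
        tree, aln, _ = duplication_bundle
        cs = ClusterSet(clusters=[[h] for h in aln.headers], provenance="computed")
        sets, cons = replicated_asr(aln, tree, wag, cs, node_id="root",
                                    thresholds=(50,), n=1, seed=0)
        profile = reconstruct(tree, aln, wag, node_id="root")
        direct = call_sequence(profile, 50).sequence
        assert sets[50].sequences == [direct]
        assert cons[50].sequence == direct

    def test_replicates_live_on_master_columns(self, wag, duplication_bundle):
        tree, aln, _ = duplication_bundle
        cs = cluster_sequences(aln, soft_max=3, seed=1)
        sets, cons = replicated_asr(aln, tree, wag, cs, node_id="root",
                                    thresholds=(10, 90), n=3, seed=5)
        for t in (10, 90):
            assert all(len(s) == aln.n_columns for s in sets[t].sequences)
            assert len(cons[t].sequence) == aln.n_columns

    def test_threshold_monotonicity_per_replicate(self, wag, duplication_bundle):
        tree, aln, _ = duplication_bundle
        cs = cluster_sequences(aln, soft_max=3, seed=1)
        sets, _ = replicated_asr(aln, tree, wag, cs, node_id="root",
                                 thresholds=(10, 50, 90), n=4, seed=2)
        for i in range(4):
            lens = [ungapped_length(sets[t].sequences[i]) for t in (10, 50, 90)]
            assert lens == sorted(lens)

    def test_end_to_end_determinism(self, wag, duplication_bundle):
        tree, aln, _ = duplication_bundle
        cs = cluster_sequences(aln, soft_max=3, seed=1)
        a = replicated_asr(aln, tree, wag, cs, thresholds=(50,), n=2, seed=8)
        b = replicated_asr(aln, tree, wag, cs, thresholds=(50,), n=2, seed=8)
        assert a[0][50].sequences == b[0][50].sequences
        assert a[1][50].sequence == b[1][50].sequence
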