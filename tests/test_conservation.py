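"""Alignment, consensus motifs and neighbor joining, with independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuromine.conservation import (
    consensus_motif,
    global_align,
    identity_distance_matrix,
    nj_tree,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestGlobalAlign:
    def test_pdh_pair_15_of_18_identical(self, peptides_by_family):
        a, b = [p for p, _ in peptides_by_family["PDH"]]
        aln = global_align(a, b)
        assert len(aln.seq_a_aligned) == 18
        assert aln.identical_positions == 15
        assert aln.identity_pct == pytest.approx(100 * 15 / 18)

    def test_self_alignment_is_100_pct(self):
        aln = global_align("APSGFLGMR", "APSGFLGMR")
        assert aln.identity_pct == 100.0

    def test_single_gap_scoring_matches_exhaustive_enumeration(self):
        # oracle: every alignment of AAA vs AA has >= 1 gap; best = 2 matches
        aln = global_align("AAA", "AA", match=1.0, mismatch=0.0, gap=-2.0)
        assert aln.score == 1 * 2 - 2
        assert aln.seq_b_aligned.count("-") == 1

    def test_score_matches_biopython_optimum(self):
        # dual route: same scoring model through Bio.Align
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        for a, b in [("NAELINSILGLPKVMNDA", "NAELINSLLGIPKVMSDA"),
                     ("FDAFTTGFGHSKR", "NFDEIDRSGFAFAKK"),
                     ("AAA", "AA"), ("QWERTY", "QRTY")]:
            assert global_align(a, b).score == aligner.score(a, b)

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=25),
           st.text(alphabet=AA, min_size=1, max_size=25))
    def test_identity_is_symmetric(self, a, b):
        assert global_align(a, b).identity_pct == pytest.approx(
            global_align(b, a).identity_pct
        )

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=25),
           st.text(alphabet=AA, min_size=1, max_size=25))
    def test_ungapping_recovers_inputs(self, a, b):
        aln = global_align(a, b)
        assert aln.seq_a_aligned.replace("-", "") == a
        assert aln.seq_b_aligned.replace("-", "") == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "A")


class TestConsensus:
    def test_pdh_consensus_has_15_letters_3_x(self, peptides_by_family):
        peps = [p for p, _ in peptides_by_family["PDH"]]
        amides = [a for _, a in peptides_by_family["PDH"]]
        motif = consensus_motif(peps, amides)
        assert len(motif.columns) == 18
        assert motif.invariant_positions == 15
        assert motif.columns.count("X") == 3
        assert motif.motif.endswith("amide")

    def test_identical_copies_have_no_x(self):
        motif = consensus_motif(["APSGFLGMR"] * 7, [True] * 7)
        assert motif.columns == "APSGFLGMR"
        assert motif.motif == "APSGFLGMRamide"

    def test_minimal_disagreement(self):
        assert consensus_motif(["AB".replace("B", "W"), "CW"]).columns == "XW"

    def test_idempotent_under_duplication(self, peptides_by_family):
        peps = [p for p, _ in peptides_by_family["PDH"]]
        once = consensus_motif(peps).columns
        twice = consensus_motif(peps + peps).columns
        assert once == twice

    def test_amide_suffix_requires_all_members(self):
        motif = consensus_motif(["APSGFLGMR", "APSGFLGMR"], [True, False])
        assert not motif.amidated

    def test_length_outliers_named(self):
        with pytest.raises(ValueError, match="outlier"):
            consensus_motif(["AAAA", "AAAA", "AAAAAAAAAAAAAAAAAA"])


def path_length(tree, a, b):
    """Oracle helper: sum of branch lengths on the a-b path in an skbio tree."""
    ta = tree.find(a)
    return ta.distance(tree.find(b))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d_AB=2, d_AC=3, d_BC=3 -> a=1, b=1, c=2 by the three-point formulas
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        result = nj_tree(["A", "B", "C"], d)
        lengths = {t.name: t.length for t in result.tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_four_taxon_additive_split_recovered(self):
        # tree ((A,B),(C,D)) with internal branch 2; oracle below brute-forces
        # the three unrooted topologies by four-point condition
        labels = ["A", "B", "C", "D"]
        ext = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = 2.0
        d = np.zeros((4, 4))
        pairs = {("A", "B"): 0.0, ("C", "D"): 0.0}
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    through = pairs.get((x, y), internal)
                    d[i, j] = d[j, i] = ext[x] + ext[y] + through
        # oracle: the correct split minimises the four-point sum
        sums = {
            "AB|CD": d[0, 1] + d[2, 3],
            "AC|BD": d[0, 2] + d[1, 3],
            "AD|BC": d[0, 3] + d[1, 2],
        }
        assert min(sums, key=sums.get) == "AB|CD"
        result = nj_tree(labels, d)
        # the AB pair must be a cherry in the reconstructed tree
        a = result.tree.find("A")
        siblings = {t.name for t in a.parent.children if t.name}
        assert siblings == {"A", "B"}

    def test_additive_matrix_path_lengths_reproduced(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 5, 9, 10],
                [5, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            float,
        )
        result = nj_tree(labels, d)
        for i, j in itertools.combinations(range(4), 2):
            assert path_length(result.tree, labels[i], labels[j]) == pytest.approx(
                d[i, j], abs=1e-9
            )

    def test_equal_distances_preserve_total_length(self):
        d = np.ones((4, 4)) - np.eye(4)
        result = nj_tree(list("ABCD"), d)
        total = sum(n.length or 0 for n in result.tree.traverse())
        # star-like tree: 4 pendant edges of 0.5 plus a zero-ish internal edge
        assert total == pytest.approx(2.0, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(list("ABC"), d)

    def test_newick_is_parseable(self):
        import dendropy

        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        result = nj_tree(["A", "B", "C"], d)
        tree = dendropy.Tree.get(data=result.newick, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B", "C"}


def test_identity_distance_matrix_from_peptides(peptides_by_family):
    peps = [p for p, _ in peptides_by_family["PDH"]]
    d = identity_distance_matrix(["p1", "p2"], peps)
    assert d[0, 0] == d[1, 1] == 0.0
    assert d[0, 1] == d[1, 0] == pytest.approx(1 - 15 / 18)
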