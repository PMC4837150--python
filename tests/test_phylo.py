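"""Alignment, NJ trees, subfamily voting, and gene-structure statistics."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix

from aatkit import phylo
from aatkit.models import GeneModel

from oracles import align_score_oracle, four_point_topology

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestGlobalAlign:
    def test_identical_sequences(self):
        seq = "MKVLAWT"
        result = phylo.global_align(seq, seq)
        assert result.identity == 1.0
        assert result.score == pytest.approx(sum(BLOSUM62[c, c] for c in seq))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            phylo.global_align("A", "")

    def test_gap_stripping_recovers_inputs(self):
        result = phylo.global_align("MKVLAWTPE", "MKVWTPE")
        assert result.aligned_a.replace("-", "") == "MKVLAWTPE"
        assert result.aligned_b.replace("-", "") == "MKVWTPE"
        assert len(result.aligned_a) == len(result.aligned_b)

    def test_score_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            a = "".join(rng.choice(aa, size=rng.integers(2, 9)))
            b = "".join(rng.choice(aa, size=rng.integers(2, 9)))
            expected = align_score_oracle(a, b, BLOSUM62, -phylo.GAP_OPEN,
                                          -phylo.GAP_EXTEND)
            assert phylo.global_align(a, b).score == pytest.approx(expected)


class TestDistanceMatrix:
    def test_symmetric_with_zero_diagonal(self):
        proteins = {"a": "MKVLAWT", "b": "MKVLAWT", "c": "MDRRAWT"}
        dm = phylo.distance_matrix(proteins)
        assert dm["a", "b"] == 0.0
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            phylo.distance_matrix({"a": "MK", "b": "MK"})


class TestNJTree:
    def _additive_matrix(self, rng):
        # random positive branch lengths on the ((a,b),(c,d)) topology
        ea, eb, ec, ed, internal = rng.uniform(0.05, 0.5, size=5)
        data = np.zeros((4, 4))
        lengths = {
            ("a", "b"): ea + eb, ("c", "d"): ec + ed,
            ("a", "c"): ea + internal + ec, ("a", "d"): ea + internal + ed,
            ("b", "c"): eb + internal + ec, ("b", "d"): eb + internal + ed,
        }
        ids = ["a", "b", "c", "d"]
        for (x, y), d in lengths.items():
            i, j = ids.index(x), ids.index(y)
            data[i, j] = data[j, i] = d
        return DistanceMatrix(data, ids)

    def test_recovers_additive_four_taxon_topologies(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            dm = self._additive_matrix(rng)
            tree = phylo.nj_tree(dm)
            expected = four_point_topology(dm, ("a", "b", "c", "d"))
            # the NJ tree's single internal split must equal the 4-point split
            import skbio

            parsed = skbio.TreeNode.read([tree.newick])
            splits = set()
            for node in parsed.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if len(side) == 2:
                    splits.add(frozenset({side, frozenset("abcd") - side}))
            assert expected in splits

    def test_three_leaf_closed_form(self):
        data = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = phylo.nj_tree(DistanceMatrix(data, ["a", "b", "c"]))
        import skbio

        parsed = skbio.TreeNode.read([tree.newick])
        lengths = {t.name: t.length for t in parsed.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)

    def test_no_negative_branch_lengths(self):
        # near-degenerate matrix that drives NJ estimates negative
        data = np.array([
            [0.0, 0.1, 0.1, 0.4],
            [0.1, 0.0, 0.1, 0.4],
            [0.1, 0.1, 0.0, 0.4],
            [0.4, 0.4, 0.4, 0.0],
        ])
        tree = phylo.nj_tree(DistanceMatrix(data, list("abcd")))
        import skbio

        parsed = skbio.TreeNode.read([tree.newick])
        assert all((n.length or 0) >= 0 for n in parsed.traverse())

    def test_asymmetric_matrix_rejected(self):
        dm = DistanceMatrix(np.array([
            [0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]), list("abc"))
        dm.data[0, 1] = 0.31  # corrupt after construction
        with pytest.raises(ValueError):
            phylo.nj_tree(dm)

    def test_bootstrap_supports_on_clean_split(self):
        rng = np.random.default_rng(7)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        def mutate(seq, n):
            seq = list(seq)
            for pos in rng.choice(len(seq), size=n, replace=False):
                seq[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            return "".join(seq)
        group1 = {f"x{i}": mutate(base, 4) for i in range(3)}
        other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        group2 = {f"y{i}": mutate(other, 4) for i in range(3)}
        proteins = {**group1, **group2}
        ids = sorted(proteins)
        alignments = {}
        n = len(ids)
        data = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aln = phylo.global_align(proteins[ids[i]], proteins[ids[j]])
                alignments[frozenset({ids[i], ids[j]})] = aln
                data[i, j] = data[j, i] = 1 - aln.identity
        tree = phylo.nj_tree(DistanceMatrix(data, ids), bootstrap_n=50, seed=1,
                             alignments=alignments)
        split = frozenset({frozenset(group1), frozenset(group2)})
        assert tree.supports, "expected support values"
        assert tree.supports.get(split, 0) >= 90

    def test_bootstrap_zero_gives_no_supports(self):
        data = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = phylo.nj_tree(DistanceMatrix(data, list("abc")), bootstrap_n=0)
        assert tree.supports == {}


@pytest.fixture(scope="module")
def references():
    rng = np.random.default_rng(13)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    refs = {}
    self_seqs = {}
    for label in phylo.SUBFAMILY_CATALOG:
        seq = "".join(rng.choice(aa, size=90))
        self_seqs[label] = seq
        refs[f"ref_{label}"] = (seq, label)
    return refs, self_seqs


class TestAssignSubfamily:
    def test_identical_query_full_support(self, references):
        refs, seqs = references
        calls = phylo.assign_subfamily({"q": seqs["AAP"]}, refs, k=1)
        assert calls[0].subfamily == "AAP"
        assert calls[0].support == 1.0
        assert calls[0].family == "AAAP"

    def test_duplicated_reference_does_not_change_call(self, references):
        refs, seqs = references
        extended = dict(refs)
        extended["ref_CAT_copy"] = refs["ref_CAT"]
        base = phylo.assign_subfamily({"q": seqs["AAP"]}, refs, k=1)
        dup = phylo.assign_subfamily({"q": seqs["AAP"]}, extended, k=1)
        assert base[0].subfamily == dup[0].subfamily

    def test_equidistant_tie_flagged(self):
        refs = {"r1": ("MKVLAWTPE", "AAP"), "r2": ("MKVLAWTPE", "CAT")}
        with pytest.warns(UserWarning):
            calls = phylo.assign_subfamily({"q": "MKVLAWTPE"}, refs, k=2)
        assert calls[0].ambiguous

    def test_missing_subfamily_warns(self):
        refs = {"r1": ("MKVLAWTPE", "AAP")}
        with pytest.warns(UserWarning, match="missing"):
            phylo.assign_subfamily({"q": "MKVLAWTPE"}, refs, k=1)


class TestGeneStructure:
    def _gene(self, exons, gene_id="g"):
        return GeneModel(gene_id=gene_id, chromosome="chr1", start=exons[0][0],
                         end=exons[-1][1], strand="+", exons=tuple(exons))

    def test_single_segment_is_intronless(self):
        stats = phylo.gene_structure_stats([self._gene([(0, 300)])])
        assert stats[0].n_introns_in_cds == 0
        assert stats[0].intronless

    def test_three_segments_two_introns(self):
        stats = phylo.gene_structure_stats(
            [self._gene([(0, 100), (200, 300), (400, 500)])])
        assert stats[0].n_introns_in_cds == 2
        assert stats[0].cds_span_bp == 500

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(gene_id="g", chromosome="chr1", start=0, end=300,
                      strand="+", exons=((0, 100), (50, 200)))
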