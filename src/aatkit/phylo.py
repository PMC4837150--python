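"""Pairwise alignment, distance trees, subfamily assignment, gene structure.

Global protein alignment is Needleman-Wunsch with affine gaps (BLOSUM62,
gap open 10, gap extend 0.5, biopython's PairwiseAligner convention where the
first gapped position costs the open penalty). Trees are neighbor-joining on
p-distances with nonparametric bootstrap support from column-resampled
alignments; subfamily membership is a k-nearest-reference vote on p-distance,
which consumes only the distance neighbourhood and therefore tolerates the
choice of tree method.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .models import GeneModel

SUBFAMILY_CATALOG = (
    "AAP", "LHT", "ProT", "GAT", "AUX", "ANT", "ATLa", "ATLb", "TTP",
    "CAT", "ACT", "PHS",
)
#: the amino acid/auxin permease group vs the amino acid-polyamine-choline group
FAMILY_GROUPS = {
    "AAP": "AAAP", "LHT": "AAAP", "ProT": "AAAP", "GAT": "AAAP", "AUX": "AAAP",
    "ANT": "AAAP", "ATLa": "AAAP", "ATLb": "AAAP", "TTP": "AAAP",
    "CAT": "APC", "ACT": "APC", "PHS": "APC",
}

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    pair_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # matches / aligned columns (no dual-gap columns occur)


@dataclass
class DistanceTree:
    newick: str
    leaves: tuple[str, ...]
    supports: dict[frozenset, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SubfamilyCall:
    gene_id: str
    subfamily: str
    family: str
    support: float
    ambiguous: bool = False


@dataclass(frozen=True)
class GeneStructureStats:
    gene_id: str
    n_exons: int
    n_introns_in_cds: int
    cds_span_bp: int
    intronless: bool


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner

_ALIGNER = _make_aligner()
_BLOSUM_ALPHABET = set(_ALIGNER.substitution_matrix.alphabet)


def global_align(a: str, b: str, pair_id: str = "pair") -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Ties between co-optimal alignments are broken deterministically by taking
    the aligner's first traceback (diagonal preferred over vertical over
    horizontal).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    for seq in (a, b):
        bad = next((c for c in seq if c not in _BLOSUM_ALPHABET), None)
        if bad is not None:
            raise ValueError(f"unknown residue {bad!r}")
    alignments = _ALIGNER.align(a, b)
    top = alignments[0]
    row_a, row_b = str(top[0]), str(top[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    columns = sum(1 for x, y in zip(row_a, row_b) if not (x == "-" and y == "-"))
    return AlignmentResult(
        pair_id=pair_id, aligned_a=row_a, aligned_b=row_b,
        score=float(top.score), identity=matches / columns,
    )


def p_distance(a: str, b: str) -> float:
    """1 - global-alignment identity; not metric (triangle violations allowed)."""
    return 1.0 - global_align(a, b).identity


def distance_matrix(proteins: dict[str, str]) -> DistanceMatrix:
    """Symmetric p-distance matrix over a set of proteins."""
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins")
    ids = list(proteins)
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(proteins[ids[i]], proteins[ids[j]])
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids)


def _bipartitions(tree: TreeNode, leaves: frozenset) -> set[frozenset]:
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({side, leaves - side}))
    return splits


def _resampled_distance(aln: AlignmentResult, rng: np.random.Generator) -> float:
    pairs = [
        (x, y) for x, y in zip(aln.aligned_a, aln.aligned_b)
        if not (x == "-" and y == "-")
    ]
    idx = rng.integers(0, len(pairs), size=len(pairs))
    matches = sum(1 for i in idx if pairs[i][0] == pairs[i][1] and pairs[i][0] != "-")
    return 1.0 - matches / len(pairs)


def nj_tree(matrix: DistanceMatrix, bootstrap_n: int = 0, seed: int = 17,
            alignments: dict[frozenset, AlignmentResult] | None = None) -> DistanceTree:
    """Neighbor-joining tree with optional bootstrap support.

    Negative NJ branch lengths are clamped to zero. Bootstrap replicates
    resample the columns of each pairwise alignment (keyed by the frozenset of
    the two leaf ids), rebuild the distance matrix and the NJ tree, and score
    each internal bipartition of the main tree by the percentage of replicates
    containing it.
    """
    data = np.asarray(matrix.data)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")
    tree = nj(matrix)
    leaves = frozenset(matrix.ids)
    supports: dict[frozenset, float] = {}
    if bootstrap_n > 0:
        if alignments is None:
            raise ValueError("bootstrap requires the pairwise alignments")
        rng = np.random.default_rng(seed)
        main_splits = _bipartitions(tree, leaves)
        counts = {split: 0 for split in main_splits}
        ids = list(matrix.ids)
        for _ in range(bootstrap_n):
            n = len(ids)
            replicate = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    aln = alignments[frozenset({ids[i], ids[j]})]
                    d = _resampled_distance(aln, rng)
                    replicate[i, j] = replicate[j, i] = d
            rep_splits = _bipartitions(nj(DistanceMatrix(replicate, ids)), leaves)
            for split in main_splits & rep_splits:
                counts[split] += 1
        supports = {s: 100.0 * c / bootstrap_n for s, c in counts.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(tip.name for tip in node.tips())
            split = frozenset({side, leaves - side})
            if split in supports:
                node.name = str(int(round(supports[split])))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buffer = _io.StringIO()
    tree.write(buffer)
    return DistanceTree(
        newick=buffer.getvalue().strip(),
        leaves=tuple(matrix.ids),
        supports=supports,
    )


def assign_subfamily(queries: dict[str, str],
                     references: dict[str, tuple[str, str]],
                     k: int = 3) -> list[SubfamilyCall]:
    """k-nearest-reference subfamily vote on p-distance.

    ``references`` maps reference id -> (sequence, subfamily label). Majority
    label among the k nearest references wins; vote ties are resolved in
    favour of the label holding the closest reference, and a residual exact
    distance tie is flagged ambiguous.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = {label for _, label in references.values()}
    missing = set(SUBFAMILY_CATALOG) - labels
    if missing:
        import warnings

        warnings.warn(f"reference set missing subfamilies: {sorted(missing)}",
                      stacklevel=2)
    calls = []
    for gene_id, seq in queries.items():
        distances = sorted(
            (p_distance(seq, ref_seq), ref_id, label)
            for ref_id, (ref_seq, label) in references.items()
        )
        nearest = distances[:k]
        votes: dict[str, int] = {}
        best_dist: dict[str, float] = {}
        for d, _, label in nearest:
            votes[label] = votes.get(label, 0) + 1
            best_dist.setdefault(label, d)
        top_votes = max(votes.values())
        tied = [label for label, v in votes.items() if v == top_votes]
        if len(tied) == 1:
            winner, ambiguous = tied[0], False
        else:
            dmin = min(best_dist[label] for label in tied)
            closest = [label for label in tied if best_dist[label] == dmin]
            winner = sorted(closest)[0]
            ambiguous = len(closest) > 1
        calls.append(SubfamilyCall(
            gene_id=gene_id, subfamily=winner,
            family=FAMILY_GROUPS.get(winner, "?"),
            support=votes[winner] / k, ambiguous=ambiguous,
        ))
    return calls


def gene_structure_stats(gene_models: list[GeneModel]) -> list[GeneStructureStats]:
    """Exon/intron statistics per gene; intronless when the CDS is one segment."""
    stats = []
    for gene in gene_models:
        prev_end = None
        for s, e in gene.exons:
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{gene.gene_id}: overlapping CDS segments")
            prev_end = e
        n_segments = len(gene.exons)
        stats.append(GeneStructureStats(
            gene_id=gene.gene_id,
            n_exons=n_segments,
            n_introns_in_cds=n_segments - 1,
            cds_span_bp=gene.exons[-1][1] - gene.exons[0][0],
            intronless=n_segments == 1,
        ))
    return stats
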