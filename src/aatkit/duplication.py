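"""Paralog detection, tandem-array grouping, collinearity chaining, mode calls.

Tandem duplicates are homologous family genes separated by at most ``max_gap``
non-family genes in the gene order of one chromosome (connected components of
the adjacency graph). WGD/segmental duplicates are detected by chaining
homologous anchor pairs between two chromosomes with a dynamic program that
maximizes anchor count under strict rank monotonicity (same or inverted
orientation) and a rank-gap bound — an auditable stand-in for the usual
collinearity-scan toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .phylo import global_align

DEFAULT_MIN_IDENTITY = 0.4
DEFAULT_MIN_SCORE = 50.0
DEFAULT_MAX_GAP = 1  # intervening non-family genes for tandem adjacency
DEFAULT_MIN_ANCHORS = 3
DEFAULT_MAX_RANK_GAP = 25


@dataclass(frozen=True)
class HomologPair:
    """Unordered homologous pair, smaller gene id stored first."""

    gene_a: str
    gene_b: str
    alignment_score: float
    identity: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-pair")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def genes(self) -> frozenset:
        return frozenset({self.gene_a, self.gene_b})


@dataclass(frozen=True)
class TandemArray:
    array_id: str
    chromosome: str
    member_genes: tuple[str, ...]  # ordered by start coordinate
    max_gap_used: int


@dataclass(frozen=True)
class CollinearBlock:
    block_id: str
    chromosome_a: str
    chromosome_b: str
    anchors: tuple[HomologPair, ...]
    orientation: str  # same | inverted


@dataclass
class DuplicationCall:
    gene_id: str
    mode: str  # tandem | wgd_segmental | both | none
    array_id: str | None = None
    block_ids: list[str] = field(default_factory=list)


GeneOrder = dict[str, list[str]]  # chromosome -> gene ids in coordinate order


def find_homolog_pairs(proteins: dict[str, str],
                       min_identity: float = DEFAULT_MIN_IDENTITY,
                       min_score: float = DEFAULT_MIN_SCORE,
                       alignments: dict | None = None) -> list[HomologPair]:
    """All-vs-all global alignment, retaining pairs above both thresholds.

    ``alignments`` may carry precomputed AlignmentResult objects keyed by the
    frozenset of the two ids; missing pairs are aligned on the fly.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    ids = sorted(proteins)
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            key = frozenset({a, b})
            aln = alignments.get(key) if alignments is not None else None
            if aln is None:
                aln = global_align(proteins[a], proteins[b], pair_id=f"{a}-{b}")
                if alignments is not None:
                    alignments[key] = aln
            if aln.identity >= min_identity and aln.score >= min_score:
                pairs.append(HomologPair(a, b, aln.score, aln.identity))
    return pairs


def _family_ranks(gene_order: GeneOrder, family: set[str]) -> dict[str, tuple[str, int, int]]:
    """gene -> (chromosome, overall rank, family-local index)."""
    ranks = {}
    for chromosome, genes in gene_order.items():
        fam_idx = 0
        for rank, gene in enumerate(genes):
            if gene in family:
                ranks[gene] = (chromosome, rank, fam_idx)
                fam_idx += 1
    return ranks


def detect_tandem(pairs: list[HomologPair], gene_order: GeneOrder,
                  max_gap: int = DEFAULT_MAX_GAP) -> list[TandemArray]:
    """Tandem arrays as connected components of near-adjacent homolog pairs.

    Two paired family genes are linked when they sit on the same chromosome
    with at most ``max_gap`` non-family genes between them. Components of size
    >= 2 become arrays, ordered and identified by chromosome and position.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    family = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    ranks = _family_ranks(gene_order, family)
    missing = family - set(ranks)
    if missing:
        raise ValueError(f"genes missing from gene order: {sorted(missing)}")
    graph = nx.Graph()
    graph.add_nodes_from(family)
    for pair in pairs:
        chrom_a, rank_a, _ = ranks[pair.gene_a]
        chrom_b, rank_b, _ = ranks[pair.gene_b]
        if chrom_a != chrom_b:
            continue
        intervening = abs(rank_a - rank_b) - 1
        non_family = intervening - _family_between(gene_order[chrom_a], rank_a, rank_b, family)
        if non_family <= max_gap:
            graph.add_edge(pair.gene_a, pair.gene_b)
    arrays = []
    components = [c for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=lambda c: min(ranks[g][:2] for g in c))
    for idx, component in enumerate(components, start=1):
        members = tuple(sorted(component, key=lambda g: ranks[g][1]))
        arrays.append(TandemArray(
            array_id=f"TA{idx:02d}",
            chromosome=ranks[members[0]][0],
            member_genes=members,
            max_gap_used=max_gap,
        ))
    return arrays


def _family_between(genes: list[str], rank_a: int, rank_b: int, family: set[str]) -> int:
    lo, hi = sorted((rank_a, rank_b))
    return sum(1 for g in genes[lo + 1 : hi] if g in family)


def _chain_dp(anchors: list[tuple[int, int, int]], sign: int,
              max_rank_gap: int) -> list[int]:
    """Longest chain of anchor indices with ranks strictly monotonic.

    ``anchors`` holds (rank_a, rank_b, index) sorted by rank_a; ``sign`` +1
    chains rank_b increasing, -1 decreasing; consecutive anchors must be
    within ``max_rank_gap`` ranks on both chromosomes. Ties prefer the chain
    whose first anchor has the smaller (rank_a, rank_b).
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ra_i, rb_i, _ = anchors[i]
        for j in range(i):
            ra_j, rb_j, _ = anchors[j]
            if ra_j >= ra_i or ra_i - ra_j > max_rank_gap:
                continue
            if sign * (rb_i - rb_j) <= 0 or abs(rb_i - rb_j) > max_rank_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not n:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -anchors[i][0], -anchors[i][1]))
    chain = []
    while end != -1:
        chain.append(anchors[end][2])
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(pairs: list[HomologPair], gene_order: GeneOrder,
                            min_anchors: int = DEFAULT_MIN_ANCHORS,
                            max_rank_gap: int = DEFAULT_MAX_RANK_GAP) -> list[CollinearBlock]:
    """Greedy extraction of disjoint monotonic anchor chains per chromosome pair.

    For every (ordered) chromosome pair the best chain (same then inverted
    orientation, more anchors wins, ties to the smaller starting ranks) is
    emitted and its anchors removed before searching again; chains shorter
    than ``min_anchors`` stop the search. Intra-chromosomal blocks are
    permitted; the two sides of one anchor are then ordered by rank.
    """
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2")
    family = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    ranks = _family_ranks(gene_order, family)
    missing = family - set(ranks)
    if missing:
        raise ValueError(f"genes missing from gene order: {sorted(missing)}")

    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for pair in pairs:
        chrom_a, rank_a, _ = ranks[pair.gene_a]
        chrom_b, rank_b, _ = ranks[pair.gene_b]
        if (chrom_a, rank_a) <= (chrom_b, rank_b):
            key, ra, rb = (chrom_a, chrom_b), rank_a, rank_b
        else:
            key, ra, rb = (chrom_b, chrom_a), rank_b, rank_a
        by_chrom_pair.setdefault(key, []).append((ra, rb, pair))

    blocks: list[CollinearBlock] = []
    raw: list[tuple[tuple, str, tuple[HomologPair, ...], str, str]] = []
    for (chrom_a, chrom_b), items in sorted(by_chrom_pair.items()):
        pool = sorted(items, key=lambda t: (t[0], t[1]))
        while True:
            indexed = [(ra, rb, i) for i, (ra, rb, _) in enumerate(pool)]
            candidates = []
            for sign, orientation in ((1, "same"), (-1, "inverted")):
                chain = _chain_dp(indexed, sign, max_rank_gap)
                if len(chain) >= min_anchors:
                    first = pool[chain[0]]
                    candidates.append((-len(chain), (first[0], first[1]), orientation, chain))
            if not candidates:
                break
            candidates.sort()
            _, first_key, orientation, chain = candidates[0]
            anchors = tuple(pool[i][2] for i in chain)
            raw.append(((chrom_a, first_key), orientation, anchors, chrom_a, chrom_b))
            used = set(chain)
            pool = [item for i, item in enumerate(pool) if i not in used]

    raw.sort(key=lambda r: (-len(r[2]), r[0]))
    for idx, (_, orientation, anchors, chrom_a, chrom_b) in enumerate(raw, start=1):
        blocks.append(CollinearBlock(
            block_id=f"CB{idx:02d}", chromosome_a=chrom_a, chromosome_b=chrom_b,
            anchors=anchors, orientation=orientation,
        ))
    return blocks


def classify_modes(arrays: list[TandemArray], blocks: list[CollinearBlock],
                   family_genes: list[str]) -> list[DuplicationCall]:
    """Per-gene duplication mode from array and block memberships."""
    array_of: dict[str, str] = {}
    for array in arrays:
        for gene in array.member_genes:
            if gene in array_of:
                raise ValueError(f"gene {gene} in two arrays")
            array_of[gene] = array.array_id
    blocks_of: dict[str, list[str]] = {}
    for block in blocks:
        for pair in block.anchors:
            for gene in (pair.gene_a, pair.gene_b):
                blocks_of.setdefault(gene, [])
                if block.block_id not in blocks_of[gene]:
                    blocks_of[gene].append(block.block_id)
    calls = []
    for gene in family_genes:
        in_array = gene in array_of
        in_block = gene in blocks_of
        if in_array and in_block:
            mode = "both"
        elif in_array:
            mode = "tandem"
        elif in_block:
            mode = "wgd_segmental"
        else:
            mode = "none"
        calls.append(DuplicationCall(
            gene_id=gene, mode=mode,
            array_id=array_of.get(gene),
            block_ids=blocks_of.get(gene, []),
        ))
    return calls


def mode_counts(calls: list[DuplicationCall]) -> dict[str, int]:
    counts = {"tandem": 0, "wgd_segmental": 0, "both": 0, "none": 0}
    for call in calls:
        counts[call.mode] += 1
    return counts
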