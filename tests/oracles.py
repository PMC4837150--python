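"""Independent brute-force oracles used to validate the main implementations.

Everything here is deliberately naive (recursion and exhaustive enumeration)
and shares no code with the package beyond the genetic code itself.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _AA[codon]


def ng86_oracle(codons_a: list[str], codons_b: list[str]) -> tuple[float, float]:
    """(Ka, Ks) by direct enumeration: per-position neighbor counting for
    sites, recursive pathway walks for differences, Jukes-Cantor correction.

    Raises ValueError on saturation.
    """

    def syn_fraction(codon: str) -> float:
        syn = 0
        for pos, nt in itertools.product(range(3), "ACGT"):
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                syn += 1
        return syn / 3.0

    def pathways(cur: str, target: str, avoid_stops: bool):
        if cur == target:
            yield (0.0, 0.0)
            return
        for pos in range(3):
            if cur[pos] == target[pos]:
                continue
            nxt = cur[:pos] + target[pos] + cur[pos + 1 :]
            if avoid_stops and nxt in _STOPS:
                continue
            step_syn = 1.0 if (nxt not in _STOPS and _aa(cur) == _aa(nxt)) else 0.0
            for syn, nonsyn in pathways(nxt, target, avoid_stops):
                yield (syn + step_syn, nonsyn + (1.0 - step_syn))

    s_a = sum(syn_fraction(c) for c in codons_a)
    s_b = sum(syn_fraction(c) for c in codons_b)
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        paths = list(pathways(ca, cb, avoid_stops=True)) or list(
            pathways(ca, cb, avoid_stops=False))
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p: float) -> float:
        if p >= 0.75:
            raise ValueError("saturated")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return jc(pn), jc(ps)


def align_score_oracle(a: str, b: str, matrix, gap_open: float,
                       gap_extend: float) -> float:
    """Best global alignment score by exhaustive path enumeration.

    Affine convention mirrors biopython's PairwiseAligner: the first position
    of a gap scores ``gap_open`` and every further position ``gap_extend``
    (both negative).
    """

    best = [-math.inf]

    def recurse(i: int, j: int, score: float, state: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if state == "da" else gap_open
            recurse(i + 1, j, score + cost, "da")
        if j < len(b):
            cost = gap_extend if state == "db" else gap_open
            recurse(i, j + 1, score + cost, "db")

    recurse(0, 0, 0.0, "m")
    return best[0]


def best_chain_oracle(anchors: list[tuple[int, int]], min_anchors: int,
                      max_rank_gap: int) -> int:
    """Size of the largest monotonic anchor subset (same or inverted
    orientation, consecutive gaps bounded on both axes); 0 if none reaches
    ``min_anchors``."""
    best = 0
    n = len(anchors)
    for mask in range(1, 2**n):
        subset = [anchors[i] for i in range(n) if mask >> i & 1]
        if len(subset) < max(min_anchors, best + 1):
            continue
        subset.sort()
        ra = [x for x, _ in subset]
        rb = [y for _, y in subset]
        if any(ra[i] >= ra[i + 1] for i in range(len(ra) - 1)):
            continue
        if any(ra[i + 1] - ra[i] > max_rank_gap for i in range(len(ra) - 1)):
            continue
        for seq in (rb, rb[::-1]):
            increasing = all(seq[i] < seq[i + 1] for i in range(len(seq) - 1))
            gaps_ok = all(abs(seq[i + 1] - seq[i]) <= max_rank_gap
                          for i in range(len(seq) - 1))
            if increasing and gaps_ok:
                best = max(best, len(subset))
                break
    return best if best >= min_anchors else 0


def four_point_topology(dm, taxa: tuple[str, str, str, str]) -> frozenset:
    """The split supported by the four-point condition on a distance matrix.

    Returns the pair grouping {frozenset({a,b}), frozenset({c,d})} whose
    cross-sum is minimal.
    """
    a, b, c, d = taxa
    sums = {
        frozenset({frozenset({a, b}), frozenset({c, d})}): dm[a, b] + dm[c, d],
        frozenset({frozenset({a, c}), frozenset({b, d})}): dm[a, c] + dm[b, d],
        frozenset({frozenset({a, d}), frozenset({b, c})}): dm[a, d] + dm[b, c],
    }
    return min(sums, key=sums.get)
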