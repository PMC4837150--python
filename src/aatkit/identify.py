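"""Family identification by position-weight-matrix domain scanning.

The diagnostic transporter domains are modelled as per-column log-odds
profiles built from seed alignments (a deliberately simple stand-in for a
profile HMM: no insert/delete states, same decision surface of score plus
profile coverage). Candidates are accepted when at least one domain hit covers
enough of the profile; hits truncated at sequence ends are reported with
coverage < 1, which is what catches fragments with short or incomplete
domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_MIN_COVERAGE = 0.5
#: placements overlapping fewer columns than this fraction of the profile are
#: not scored; keeps end-truncated placements meaningful while excluding
#: single-column overlaps that would dominate a null calibration
MIN_SCAN_OVERLAP = 0.25


@dataclass(frozen=True)
class DomainProfile:
    """Log-odds profile over the 20 standard amino acids."""

    profile_id: str
    log_odds: np.ndarray  # (profile_length, 20), bits

    @property
    def profile_length(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    profile_id: str
    start: int  # 0-based half-open protein coordinates
    end: int
    score: float  # summed log-odds, bits
    coverage: float  # matched columns / profile_length


@dataclass
class FamilyAssignment:
    gene_id: str
    accepted: bool
    rejection_reason: str | None = None  # None | short_or_incomplete_domain | no_hit
    assigned_name: str | None = None
    subfamily: str | None = None
    best_score: float | None = None
    best_coverage: float | None = None
    hits: list[DomainHit] = field(default_factory=list)


def build_profile(profile_id: str, seed_alignment: list[str],
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> DomainProfile:
    """Build a log-odds profile from an aligned seed set.

    Columns with more than 50% gaps are dropped; remaining gap characters are
    ignored in the counts. Log-odds are against a uniform 1/20 background with
    a per-cell pseudocount (floored at 1e-3 so single-observation columns stay
    finite).
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    lengths = {len(s) for s in seed_alignment}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    pseudocount = max(pseudocount, 1e-3)
    n_seq = len(seed_alignment)
    columns = []
    for col in zip(*seed_alignment):
        gaps = sum(1 for c in col if c == "-")
        if gaps * 2 > n_seq:
            continue
        counts = np.full(20, pseudocount)
        for c in col:
            if c == "-":
                continue
            try:
                counts[_AA_INDEX[c]] += 1.0
            except KeyError:
                raise ValueError(f"non-amino-acid symbol {c!r} in seed alignment") from None
        freqs = counts / counts.sum()
        columns.append(np.log2(freqs * 20.0))
    if len(columns) < 10:
        raise ValueError(f"profile too short after gap-column removal: {len(columns)}")
    return DomainProfile(profile_id=profile_id, log_odds=np.array(columns))


def _encode(protein: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in protein], dtype=np.intp)
    except KeyError:
        bad = next(c for c in protein if c not in _AA_INDEX)
        raise ValueError(f"non-amino-acid symbol {bad!r} in protein sequence") from None


def scan_domains(gene_id: str, protein: str, profiles: list[DomainProfile],
                 score_thresholds: dict[str, float]) -> list[DomainHit]:
    """Best-scoring non-overlapping placements of each profile on one protein.

    Placements may run off either sequence end (coverage < 1); only columns
    inside the sequence are scored. Hits below the per-profile threshold are
    discarded; surviving hits of one profile are selected greedily by score
    with overlapping placements suppressed.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    encoded = _encode(protein)
    n = len(protein)
    hits: list[DomainHit] = []
    for profile in profiles:
        threshold = score_thresholds[profile.profile_id]
        length = profile.profile_length
        min_overlap = max(10, math.ceil(MIN_SCAN_OVERLAP * length))
        candidates = []
        for offset in range(-(length - min_overlap), n - min_overlap + 1):
            col_start = max(0, -offset)
            col_end = min(length, n - offset)
            cols = np.arange(col_start, col_end)
            residues = encoded[offset + col_start : offset + col_end]
            score = float(profile.log_odds[cols, residues].sum())
            if score >= threshold:
                coverage = (col_end - col_start) / length
                candidates.append(DomainHit(
                    gene_id=gene_id, profile_id=profile.profile_id,
                    start=offset + col_start, end=offset + col_end,
                    score=score, coverage=coverage,
                ))
        candidates.sort(key=lambda h: (-h.score, h.start))
        chosen: list[DomainHit] = []
        for hit in candidates:
            if all(hit.end <= c.start or hit.start >= c.end for c in chosen):
                chosen.append(hit)
        hits.extend(sorted(chosen, key=lambda h: h.start))
    return hits


def calibrate_threshold(profile: DomainProfile, n_sequences: int = 500,
                        sequence_length: int = 300, quantile: float = 0.99,
                        seed: int = 17) -> float:
    """Score threshold as a quantile of the best-hit null on random proteins.

    Random sequences are uniform over the 20 amino acids; for each, the best
    placement score (same placement rules as ``scan_domains``) enters the null
    distribution.
    """
    rng = np.random.default_rng(seed)
    length = profile.profile_length
    min_overlap = max(10, math.ceil(MIN_SCAN_OVERLAP * length))
    best_scores = np.empty(n_sequences)
    for i in range(n_sequences):
        encoded = rng.integers(0, 20, size=sequence_length)
        best = -math.inf
        for offset in range(-(length - min_overlap), sequence_length - min_overlap + 1):
            col_start = max(0, -offset)
            col_end = min(length, sequence_length - offset)
            cols = np.arange(col_start, col_end)
            score = profile.log_odds[cols, encoded[offset + col_start : offset + col_end]].sum()
            best = max(best, float(score))
        best_scores[i] = best
    return float(np.quantile(best_scores, quantile))


def filter_candidates(hits_by_gene: dict[str, list[DomainHit]],
                      min_coverage: float = DEFAULT_MIN_COVERAGE) -> list[FamilyAssignment]:
    """Accept genes with at least one sufficiently complete domain hit.

    A gene with hits but none reaching ``min_coverage`` is rejected as
    ``short_or_incomplete_domain``; a gene with no hits at all as ``no_hit``.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must be in (0, 1]")
    assignments = []
    for gene_id, hits in hits_by_gene.items():
        best = max(hits, key=lambda h: h.coverage, default=None)
        if best is None:
            assignments.append(FamilyAssignment(gene_id, False, "no_hit"))
        elif best.coverage >= min_coverage:
            top = max(hits, key=lambda h: h.score)
            assignments.append(FamilyAssignment(
                gene_id, True, None,
                best_score=top.score, best_coverage=best.coverage, hits=list(hits),
            ))
        else:
            top = max(hits, key=lambda h: h.score)
            assignments.append(FamilyAssignment(
                gene_id, False, "short_or_incomplete_domain",
                best_score=top.score, best_coverage=best.coverage, hits=list(hits),
            ))
    return assignments


def assign_names(assignments: list[FamilyAssignment],
                 subfamilies: dict[str, str],
                 coordinates: dict[str, tuple[str, int]]) -> list[FamilyAssignment]:
    """Systematic names: subfamily prefix + 1-based rank by (chromosome, start).

    Only accepted genes are named; re-running on the same input yields the
    same names because the ordering key is deterministic.
    """
    accepted = [a for a in assignments if a.accepted]
    seen: set[str] = set()
    for a in accepted:
        if a.gene_id in seen:
            raise ValueError(f"duplicate gene_id {a.gene_id!r}")
        seen.add(a.gene_id)
        if a.gene_id not in subfamilies:
            raise ValueError(f"gene {a.gene_id!r} has no subfamily label")
        if a.gene_id not in coordinates:
            raise ValueError(f"gene {a.gene_id!r} has no coordinates")
        a.subfamily = subfamilies[a.gene_id]
    by_subfamily: dict[str, list[FamilyAssignment]] = {}
    for a in accepted:
        by_subfamily.setdefault(a.subfamily, []).append(a)
    for subfamily, members in by_subfamily.items():
        members.sort(key=lambda a: coordinates[a.gene_id])
        for rank, a in enumerate(members, start=1):
            a.assigned_name = f"{subfamily}{rank}"
    return assignments
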