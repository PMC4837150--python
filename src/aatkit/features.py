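"""Per-protein descriptors: length, Mw, pI, transmembrane spans, motif hits.

Molecular weight (average isotopic masses plus one water) and isoelectric
point (bisection on the Henderson-Hasselbalch net charge, Bjellqvist pKa set)
come from biopython's ProtParam. Transmembrane spans use a sliding-window
Kyte-Doolittle hydropathy scan — a deliberately transparent surrogate for an
HMM-based TM predictor that preserves the downstream contract of a per-protein
span count, possibly zero. The packaged catalog of 20 conserved family motifs
is matched by exact-width Hamming scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .identify import AMINO_ACIDS

# pinned TM-scan defaults: 19-residue window, hydropathy cutoff 1.6,
# spans closer than 5 residues merged, minimum span length 15
TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MERGE_GAP = 5
TM_MIN_LENGTH = 15

PKA_SET = "Bjellqvist (biopython ProtParam)"  # pinned for reproducibility


@dataclass
class ProteinStats:
    gene_id: str
    length: int
    mw_kda: float
    pi: float
    tm_spans: list[tuple[int, int]]  # 0-based half-open

    @property
    def tm_count(self) -> int:
        return len(self.tm_spans)


@dataclass(frozen=True)
class MotifOccurrence:
    gene_id: str
    motif_id: int
    start: int  # 0-based
    mismatches: int


def _check_sequence(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein sequence")
    bad = next((c for c in protein if c not in AMINO_ACIDS), None)
    if bad is not None:
        raise ValueError(f"non-standard residue {bad!r}")


def isoelectric_point(protein: str) -> float:
    """pI by bisection of the Bjellqvist net charge over the full pH range.

    The library's own pi() bisects only within [4.05, 12] and therefore
    clamps strongly acidic or basic peptides to those bounds; solving the
    charge root directly on [0, 14] (to |charge| well below 1e-4) removes the
    clamp while keeping the same pKa set.
    """
    from scipy.optimize import brentq

    charge = ProteinAnalysis(protein).charge_at_pH
    return float(brentq(charge, 0.0, 14.0, xtol=1e-8))


def compute_stats(gene_id: str, protein: str,
                  tm_window: int = TM_WINDOW,
                  tm_threshold: float = TM_THRESHOLD) -> ProteinStats:
    """Length, molecular weight (kDa), pI and TM spans for one protein."""
    _check_sequence(protein)
    analysis = ProteinAnalysis(protein)
    return ProteinStats(
        gene_id=gene_id,
        length=len(protein),
        mw_kda=analysis.molecular_weight() / 1000.0,
        pi=isoelectric_point(protein),
        tm_spans=predict_tm_regions(protein, window=tm_window, threshold=tm_threshold),
    )


def predict_tm_regions(protein: str, window: int = TM_WINDOW,
                       threshold: float = TM_THRESHOLD,
                       merge_gap: int = TM_MERGE_GAP,
                       min_length: int = TM_MIN_LENGTH) -> list[tuple[int, int]]:
    """Maximal hydrophobic runs under a windowed Kyte-Doolittle mean.

    A residue belongs to a run when the mean hydropathy of the window centred
    on it is >= ``threshold``; runs separated by <= ``merge_gap`` residues are
    merged, and merged runs shorter than ``min_length`` are dropped. Sequences
    shorter than the window yield no spans.
    """
    if window < 7 or window % 2 == 0:
        raise ValueError("window must be odd and >= 7")
    _check_sequence(protein)
    n = len(protein)
    if n < window:
        return []
    values = np.array([KYTE_DOOLITTLE[c] for c in protein])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    hot = np.zeros(n, dtype=bool)
    hot[half : half + len(means)] = means >= threshold

    spans: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(hot):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, n))

    merged: list[tuple[int, int]] = []
    for span in spans:
        if merged and span[0] - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], span[1])
        else:
            merged.append(span)
    return [s for s in merged if s[1] - s[0] >= min_length]


def load_motif_catalog() -> pd.DataFrame:
    """Packaged catalog of the 20 conserved family motifs.

    Each row carries motif_id, width, sequence; the stored width is checked
    against the sequence length at load and any disagreement is flagged as an
    error rather than silently corrected.
    """
    with resources.files("aatkit.data").joinpath("motifs.tsv").open() as fh:
        catalog = pd.read_csv(fh, sep="\t")
    bad = catalog[catalog["width"] != catalog["sequence"].str.len()]
    if len(bad):
        raise ValueError(
            "motif catalog width/sequence disagreement: "
            + ", ".join(str(m) for m in bad["motif_id"])
        )
    return catalog


def scan_motifs(gene_id: str, protein: str, catalog: pd.DataFrame,
                max_mismatch_fraction: float = 0.10) -> list[MotifOccurrence]:
    """All motif placements within the per-motif Hamming mismatch budget.

    The budget defaults to 10% of motif width, rounded down. Overlapping
    placements of the same motif are deduplicated to the best (fewest
    mismatches, then leftmost). Motifs longer than the protein simply yield no
    occurrence.
    """
    _check_sequence(protein)
    encoded = np.frombuffer(protein.encode(), dtype=np.uint8)
    occurrences: list[MotifOccurrence] = []
    for rec in catalog.itertuples(index=False):
        width = int(rec.width)
        motif = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        budget = int(max_mismatch_fraction * width)
        if width > len(protein):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(encoded, width)
        mismatch_counts = (windows != motif).sum(axis=1)
        candidates = sorted(
            (int(m), int(s)) for s, m in enumerate(mismatch_counts) if m <= budget
        )
        chosen: list[tuple[int, int]] = []
        for mismatches, start in candidates:
            if all(start + width <= s or start >= s + width for _, s in chosen):
                chosen.append((mismatches, start))
        occurrences.extend(
            MotifOccurrence(gene_id, int(rec.motif_id), start, mismatches)
            for mismatches, start in sorted(chosen, key=lambda c: c[1])
        )
    return occurrences
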