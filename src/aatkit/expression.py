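"""RPKM normalization and expression-pattern classification.

RPKM = count / (mRNA length in kb) / (mapped reads in millions). A gene is
silent when every tissue is below the detection threshold (default RPKM 1),
uniform when detected with a max/min fold range under the fold cutoff
(default 2, the conventional "less than twofold variation" rule for genes
that are not developmentally regulated), otherwise regulated, with preferred
tissues called where one tissue dominates the runner-up.

Duplicated pairs fall into three divergence types: type I — both copies share
the pattern at comparable levels; type II — shared pattern but one copy
uniformly higher; type III — divergent patterns across tissues. The calls use
Pearson correlation of log2(RPKM + pseudocount) profiles plus the per-tissue
log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DETECTION_THRESHOLD = 1.0  # RPKM
FOLD_CUTOFF = 2.0
PREFERENCE_RATIO = 2.0
LOG_PSEUDOCOUNT = 0.1
R_CUTOFF = 0.8
SHIFT_CUTOFF = 1.0  # log2 units


@dataclass
class ExpressionMatrix:
    """RPKM values (genes x tissues) plus the inputs they derive from."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame
    mrna_lengths: pd.Series  # bp
    library_sizes: pd.Series  # mapped reads per tissue

    @property
    def tissues(self) -> list[str]:
        return list(self.rpkm.columns)


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    status: str  # silent | uniform | regulated
    preferred_tissues: tuple[str, ...]
    fold_range: float | None


@dataclass(frozen=True)
class PairExpressionType:
    pair_id: str
    divergence_type: str  # I_same_pattern | II_magnitude_shift | III_divergent
    correlation: float | None
    magnitude_ratio: float  # median per-tissue log2 ratio (b over a)
    higher_member: str | None = None
    silent_member: bool = False


def rpkm(counts: pd.DataFrame, mrna_lengths: pd.Series,
         library_sizes: pd.Series) -> ExpressionMatrix:
    """Reads per kilobase of mRNA per million mapped reads."""
    if (counts.values < 0).any():
        raise ValueError("negative count")
    lengths = mrna_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive mRNA length")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("every tissue needs a positive library size")
    values = counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)
    return ExpressionMatrix(
        rpkm=values, counts=counts.copy(),
        mrna_lengths=lengths.astype(float), library_sizes=libs.astype(float),
    )


def classify_regulation(gene_id: str, profile: pd.Series,
                        detection_threshold: float = DETECTION_THRESHOLD,
                        fold_cutoff: float = FOLD_CUTOFF,
                        preference_ratio: float = PREFERENCE_RATIO) -> ExpressionClass:
    """Silent / uniform / regulated call for one gene's tissue profile.

    The fold range divides the maximum by the detection-adjusted minimum so
    that near-zero tissues do not blow it up. A preferred tissue is one whose
    value reaches ``preference_ratio`` times the second-highest tissue.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 tissues")
    values = profile.astype(float)
    if (values < detection_threshold).all():
        return ExpressionClass(gene_id, "silent", (), None)
    fold_range = values.max() / max(values.min(), detection_threshold)
    status = "uniform" if fold_range < fold_cutoff else "regulated"
    ranked = values.sort_values(ascending=False)
    second = ranked.iloc[1]
    preferred = tuple(
        t for t, v in values.items()
        if v >= detection_threshold and v >= preference_ratio * max(second, detection_threshold)
    )
    return ExpressionClass(gene_id, status, preferred, float(fold_range))


def classify_pair_divergence(pair_id: str, profile_a: pd.Series, profile_b: pd.Series,
                             r_cutoff: float = R_CUTOFF,
                             shift_cutoff: float = SHIFT_CUTOFF,
                             pseudocount: float = LOG_PSEUDOCOUNT,
                             detection_threshold: float = DETECTION_THRESHOLD,
                             member_a: str = "a", member_b: str = "b") -> PairExpressionType:
    """Three-way divergence type for a duplicated pair.

    Type I: correlated profiles without a systematic magnitude shift.
    Type II: correlated profiles with one member higher in every tissue and a
    median |log2 ratio| beyond ``shift_cutoff``.
    Type III: everything else (divergent patterns). A zero-variance profile
    leaves the correlation undefined; the call then falls through to the
    magnitude rules alone.
    """
    if list(profile_a.index) != list(profile_b.index):
        raise ValueError("tissue orders differ")
    a = np.log2(profile_a.astype(float) + pseudocount)
    b = np.log2(profile_b.astype(float) + pseudocount)
    silent_member = (
        (profile_a < detection_threshold).all() or (profile_b < detection_threshold).all()
    )
    if a.std() == 0 or b.std() == 0:
        r = None
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    ratio = b - a
    median_ratio = float(ratio.median())
    # ties (identical values in a tissue) do not break one-sidedness; the
    # shift cutoff on the median already demands a real magnitude difference
    one_side = (ratio >= 0).all() or (ratio <= 0).all()
    correlated = r is None or r >= r_cutoff
    if correlated and abs(median_ratio) < shift_cutoff:
        divergence = "I_same_pattern"
        higher = None
    elif correlated and one_side and abs(median_ratio) >= shift_cutoff:
        divergence = "II_magnitude_shift"
        higher = member_b if median_ratio > 0 else member_a
    else:
        divergence = "III_divergent"
        higher = None
    return PairExpressionType(
        pair_id=pair_id, divergence_type=divergence, correlation=r,
        magnitude_ratio=median_ratio, higher_member=higher,
        silent_member=bool(silent_member),
    )


@dataclass
class ExpressionSummary:
    subfamily_means: pd.DataFrame  # subfamily x tissue mean RPKM
    status_counts: dict[str, int]
    pair_type_counts: dict[str, int]
    classes: list[ExpressionClass] = field(default_factory=list)
    pair_types: list[PairExpressionType] = field(default_factory=list)


def summarize_family_expression(matrix: ExpressionMatrix,
                                subfamilies: dict[str, str],
                                pairs: list[tuple[str, str, str]],
                                detection_threshold: float = DETECTION_THRESHOLD,
                                fold_cutoff: float = FOLD_CUTOFF,
                                heatmap_path: str | None = None) -> ExpressionSummary:
    """Family-level tallies: per-subfamily means, status counts, pair types.

    ``pairs`` holds (pair_id, gene_a, gene_b) tuples; pairs with a silent
    member are tallied separately rather than typed. Optionally renders a
    heatmap with genes ordered by subfamily.
    """
    unknown = [g for g in subfamilies if g not in matrix.rpkm.index]
    if unknown:
        raise ValueError(f"genes missing from expression matrix: {unknown[:5]}")
    classes = [
        classify_regulation(gene, matrix.rpkm.loc[gene],
                            detection_threshold=detection_threshold,
                            fold_cutoff=fold_cutoff)
        for gene in subfamilies
    ]
    status_counts = {"silent": 0, "uniform": 0, "regulated": 0}
    for cls in classes:
        status_counts[cls.status] += 1

    pair_types = []
    pair_type_counts = {
        "I_same_pattern": 0, "II_magnitude_shift": 0, "III_divergent": 0,
        "silent_member": 0,
    }
    for pair_id, gene_a, gene_b in pairs:
        for gene in (gene_a, gene_b):
            if gene not in matrix.rpkm.index:
                raise ValueError(f"pair gene missing from matrix: {gene}")
        call = classify_pair_divergence(
            pair_id, matrix.rpkm.loc[gene_a], matrix.rpkm.loc[gene_b],
            detection_threshold=detection_threshold,
            member_a=gene_a, member_b=gene_b,
        )
        pair_types.append(call)
        if call.silent_member:
            pair_type_counts["silent_member"] += 1
        else:
            pair_type_counts[call.divergence_type] += 1

    grouped = matrix.rpkm.loc[list(subfamilies)].groupby(
        pd.Series(subfamilies), sort=True
    ).mean()

    if heatmap_path is not None:
        _render_heatmap(matrix, subfamilies, heatmap_path)

    return ExpressionSummary(
        subfamily_means=grouped,
        status_counts=status_counts,
        pair_type_counts=pair_type_counts,
        classes=classes,
        pair_types=pair_types,
    )


def _render_heatmap(matrix: ExpressionMatrix, subfamilies: dict[str, str],
                    path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sorted(subfamilies, key=lambda g: (subfamilies[g], g))
    data = np.log2(matrix.rpkm.loc[order] + LOG_PSEUDOCOUNT)
    fig, ax = plt.subplots(figsize=(6, max(4, 0.045 * len(order))))
    im = ax.imshow(data.values, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title("log2(RPKM + 0.1), genes ordered by subfamily")
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
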