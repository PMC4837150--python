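"""End-to-end survey orchestration on a bundle directory.

Stage order: identification -> subfamily classification -> naming -> protein
features -> duplication analysis -> Ka/Ks dating of duplicate pairs ->
gene-structure statistics -> expression analysis -> summary. Every stage
writes a machine-readable table, and an identical configuration plus inputs
produces a byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import duplication, expression, features, identify, kaks, phylo
from .synthetic import SyntheticGenomeBundle, read_bundle, translate_cds

logger = logging.getLogger("aatkit")


@dataclass
class PipelineConfig:
    bundle_dir: str | None = None
    out_dir: str | None = None
    min_coverage: float = identify.DEFAULT_MIN_COVERAGE
    null_quantile: float = 0.99
    min_identity: float = duplication.DEFAULT_MIN_IDENTITY
    min_score: float = duplication.DEFAULT_MIN_SCORE
    max_gap: int = duplication.DEFAULT_MAX_GAP
    min_anchors: int = duplication.DEFAULT_MIN_ANCHORS
    max_rank_gap: int = duplication.DEFAULT_MAX_RANK_GAP
    lambda_rate: float = kaks.DEFAULT_LAMBDA
    recent_cutoff_my: float = 25.0
    k_neighbors: int = 3
    detection_threshold: float = expression.DETECTION_THRESHOLD
    fold_cutoff: float = expression.FOLD_CUTOFF
    r_cutoff: float = expression.R_CUTOFF
    shift_cutoff: float = expression.SHIFT_CUTOFF
    bootstrap_n: int = 0  # full-family NJ bootstrap is opt-in (costly)
    seed: int = 17


@dataclass
class PipelineResult:
    config: PipelineConfig
    assignments: list[identify.FamilyAssignment]
    subfamily_calls: list[phylo.SubfamilyCall]
    protein_stats: list[features.ProteinStats]
    motif_hits: list[features.MotifOccurrence]
    homolog_pairs: list[duplication.HomologPair]
    tandem_arrays: list[duplication.TandemArray]
    collinear_blocks: list[duplication.CollinearBlock]
    duplication_calls: list[duplication.DuplicationCall]
    kaks_results: list[kaks.KaKsResult]
    structure_stats: list[phylo.GeneStructureStats]
    tree: phylo.DistanceTree | None
    expression_matrix: expression.ExpressionMatrix
    expression_summary: expression.ExpressionSummary
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return decorator


@_stage("identify")
def _run_identify(bundle: SyntheticGenomeBundle, config: PipelineConfig):
    profiles = [
        identify.build_profile(domain_id, seeds)
        for domain_id, seeds in sorted(bundle.domain_profiles.items())
    ]
    thresholds = {
        p.profile_id: identify.calibrate_threshold(
            p, quantile=config.null_quantile, seed=config.seed)
        for p in profiles
    }
    hits_by_gene = {
        gene_id: identify.scan_domains(gene_id, protein, profiles, thresholds)
        for gene_id, protein in bundle.proteins.items()
    }
    return identify.filter_candidates(hits_by_gene, min_coverage=config.min_coverage)


def run_pipeline(bundle: SyntheticGenomeBundle | str | Path,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full survey; see module docstring for the stage order."""
    config = config or PipelineConfig()
    if not isinstance(bundle, SyntheticGenomeBundle):
        config.bundle_dir = str(bundle)
        bundle = read_bundle(bundle)
    proteins = bundle.proteins
    coordinates = {g.gene_id: (g.chromosome, g.start) for g in bundle.gene_models}

    assignments = _run_identify(bundle, config)
    accepted = sorted(a.gene_id for a in assignments if a.accepted)
    family_proteins = {g: proteins[g] for g in accepted}

    calls = phylo.assign_subfamily(
        family_proteins, bundle.reference_proteins, k=config.k_neighbors)
    subfamily_of = {c.gene_id: c.subfamily for c in calls}
    identify.assign_names(assignments, subfamily_of, coordinates)

    protein_stats = [
        features.compute_stats(g, family_proteins[g]) for g in accepted]
    catalog = features.load_motif_catalog()
    motif_hits = [
        hit for g in accepted for hit in features.scan_motifs(g, family_proteins[g], catalog)
    ]

    alignment_cache: dict = {}
    pairs = duplication.find_homolog_pairs(
        family_proteins, min_identity=config.min_identity,
        min_score=config.min_score, alignments=alignment_cache)
    gene_order = bundle.gene_order()
    arrays = duplication.detect_tandem(pairs, gene_order, max_gap=config.max_gap)
    array_of: dict[str, str] = {
        g: a.array_id for a in arrays for g in a.member_genes}
    # tandem pairs are masked before collinearity chaining, as collinearity
    # scanners conventionally do, so arrays cannot masquerade as tiny blocks
    anchor_pairs = [
        p for p in pairs
        if array_of.get(p.gene_a) is None or array_of.get(p.gene_a) != array_of.get(p.gene_b)
    ]
    blocks = duplication.detect_collinear_blocks(
        anchor_pairs, gene_order,
        min_anchors=config.min_anchors, max_rank_gap=config.max_rank_gap)
    dup_calls = duplication.classify_modes(arrays, blocks, accepted)

    kaks_results = []
    cds = bundle.cds
    for block in blocks:
        for pair in block.anchors:
            key = frozenset({pair.gene_a, pair.gene_b})
            aln = alignment_cache[key]
            a, b = sorted(key)
            codon_aln = kaks.codon_align(
                cds[a], cds[b], aln.aligned_a, aln.aligned_b,
                pair_id=f"{a}-{b}")
            kaks_results.append(kaks.evaluate_pair(
                codon_aln, lambda_rate=config.lambda_rate,
                recent_cutoff_my=config.recent_cutoff_my))

    structure_stats = phylo.gene_structure_stats(
        [g for g in bundle.gene_models if g.gene_id in family_proteins])

    tree = None
    if len(family_proteins) >= 3:
        for i, a in enumerate(accepted):
            for b in accepted[i + 1 :]:
                key = frozenset({a, b})
                if key not in alignment_cache:
                    alignment_cache[key] = phylo.global_align(
                        proteins[a], proteins[b], pair_id=f"{a}-{b}")
        import numpy as np
        from skbio import DistanceMatrix

        n = len(accepted)
        data = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - alignment_cache[frozenset({accepted[i], accepted[j]})].identity
                data[i, j] = data[j, i] = d
        tree = phylo.nj_tree(
            DistanceMatrix(data, accepted), bootstrap_n=config.bootstrap_n,
            seed=config.seed, alignments=alignment_cache)

    matrix = expression.rpkm(
        bundle.counts,
        pd.Series({g.gene_id: len(g.cds) for g in bundle.gene_models}),
        bundle.library_sizes,
    )
    block_pairs = [
        (f"{block.block_id}:{p.gene_a}-{p.gene_b}", p.gene_a, p.gene_b)
        for block in blocks for p in block.anchors
    ]
    expr_summary = expression.summarize_family_expression(
        matrix, subfamily_of, block_pairs,
        detection_threshold=config.detection_threshold,
        fold_cutoff=config.fold_cutoff,
    )

    name_of = {a.gene_id: a.assigned_name for a in assignments if a.accepted}
    summary = {
        "family_size": len(accepted),
        "n_candidates": sum(1 for a in assignments if a.rejection_reason != "no_hit"),
        "n_rejected_incomplete": sum(
            1 for a in assignments
            if a.rejection_reason == "short_or_incomplete_domain"),
        "subfamily_counts": _tally(c.subfamily for c in calls),
        "duplication_modes": duplication.mode_counts(dup_calls),
        "n_tandem_arrays": len(arrays),
        "n_collinear_blocks": len(blocks),
        "selection": _tally(r.selection for r in kaks_results),
        "wgd_rounds": _tally(r.wgd_round for r in kaks_results),
        "expression_status": expr_summary.status_counts,
        "pair_types": expr_summary.pair_type_counts,
        "n_intronless": sum(1 for s in structure_stats if s.intronless),
        "example_names": [name_of[g] for g in accepted[:3]],
    }

    result = PipelineResult(
        config=config, assignments=assignments, subfamily_calls=calls,
        protein_stats=protein_stats, motif_hits=motif_hits,
        homolog_pairs=pairs, tandem_arrays=arrays, collinear_blocks=blocks,
        duplication_calls=dup_calls, kaks_results=kaks_results,
        structure_stats=structure_stats, tree=tree,
        expression_matrix=matrix, expression_summary=expr_summary,
        summary=summary,
    )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def _tally(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in items:
        out[item] = out.get(item, 0) + 1
    return dict(sorted(out.items()))


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([
        {"gene_id": a.gene_id, "accepted": a.accepted,
         "reason": a.rejection_reason or "", "name": a.assigned_name or "",
         "subfamily": a.subfamily or "", "best_score": a.best_score,
         "best_coverage": a.best_coverage}
        for a in result.assignments
    ]).to_csv(out / "assignments.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"gene_id": s.gene_id, "length": s.length, "mw_kda": round(s.mw_kda, 3),
         "pi": round(s.pi, 2), "tm_count": s.tm_count,
         "tm_spans": ";".join(f"{a}-{b}" for a, b in s.tm_spans)}
        for s in result.protein_stats
    ]).to_csv(out / "stats.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"gene_id": m.gene_id, "motif_id": m.motif_id, "start": m.start,
         "mismatches": m.mismatches}
        for m in result.motif_hits
    ]).to_csv(out / "motif_hits.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"gene_id": c.gene_id, "mode": c.mode, "array_id": c.array_id or "",
         "block_ids": ";".join(c.block_ids)}
        for c in result.duplication_calls
    ]).to_csv(out / "duplications.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"block_id": b.block_id, "chromosome_a": b.chromosome_a,
         "chromosome_b": b.chromosome_b, "orientation": b.orientation,
         "n_anchors": len(b.anchors),
         "anchors": ";".join(f"{p.gene_a}|{p.gene_b}" for p in b.anchors)}
        for b in result.collinear_blocks
    ]).to_csv(out / "blocks.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"pair": r.pair_id, "ka": r.ka, "ks": r.ks, "ratio": r.ratio,
         "time_my": r.time_my, "selection": r.selection, "wgd_round": r.wgd_round,
         "saturated": r.ka_saturated or r.ks_saturated}
        for r in result.kaks_results
    ]).to_csv(out / "kaks.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"gene_id": c.gene_id, "subfamily": c.subfamily, "family": c.family,
         "support": c.support, "ambiguous": c.ambiguous}
        for c in result.subfamily_calls
    ]).to_csv(out / "subfamilies.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"gene_id": s.gene_id, "n_exons": s.n_exons,
         "n_introns_in_cds": s.n_introns_in_cds, "cds_span_bp": s.cds_span_bp,
         "intronless": s.intronless}
        for s in result.structure_stats
    ]).to_csv(out / "structures.tsv", sep="\t", index=False)

    result.expression_matrix.rpkm.round(4).to_csv(out / "rpkm.tsv", sep="\t")
    pd.DataFrame([
        {"gene_id": c.gene_id, "status": c.status,
         "preferred_tissues": ";".join(c.preferred_tissues),
         "fold_range": c.fold_range}
        for c in result.expression_summary.classes
    ]).to_csv(out / "expression_classes.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"pair": p.pair_id, "type": p.divergence_type, "correlation": p.correlation,
         "median_log2_ratio": p.magnitude_ratio, "higher": p.higher_member or "",
         "silent_member": p.silent_member}
        for p in result.expression_summary.pair_types
    ]).to_csv(out / "pair_types.tsv", sep="\t", index=False)

    if result.tree is not None:
        (out / "tree.nwk").write_text(result.tree.newick + "\n")

    expression._render_heatmap(
        result.expression_matrix,
        {c.gene_id: c.subfamily for c in result.subfamily_calls},
        str(out / "heatmap.svg"))

    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    (out / "effective_config.json").write_text(
        json.dumps(dataclasses.asdict(result.config), indent=2, sort_keys=True) + "\n")
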