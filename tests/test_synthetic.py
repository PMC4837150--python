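"""Generator contracts: determinism, planted structure, divergence, I/O."""

import numpy as np
import pytest
from scipy import stats as scistats

from aatkit import kaks, synthetic
from aatkit.models import reverse_complement
from aatkit.synthetic import GeneratorConfig, evolve_cds, translate_cds


def _ng86(cds_a, cds_b):
    columns = tuple(
        (cds_a[i : i + 3], cds_b[i : i + 3]) for i in range(0, len(cds_a), 3))
    return kaks.ng86_kaks(kaks.CodonAlignment("p", columns))


@pytest.fixture(scope="module")
def base_cds():
    rng = np.random.default_rng(2)
    sense = list(kaks.SENSE_CODONS)
    return "".join(sense[i] for i in rng.integers(0, len(sense), 500))


class TestEvolveCds:
    def test_zero_targets_identity(self, base_cds):
        assert evolve_cds(base_cds, 0.0, 0.0, seed=1) == base_cds

    def test_synonymous_only_preserves_protein(self, base_cds):
        evolved = evolve_cds(base_cds, 0.3, 0.0, seed=2)
        assert translate_cds(evolved) == translate_cds(base_cds)
        assert evolved != base_cds

    def test_no_stop_codons_introduced(self, base_cds):
        evolved = evolve_cds(base_cds, 0.5, 0.3, seed=3)
        translate_cds(evolved)  # raises on any internal stop

    def test_ks_round_trip(self, base_cds):
        """Planted Ks 0.2 on 500 codons recovered by NG86 within +-0.05."""
        errors = []
        for seed in range(20):
            evolved = evolve_cds(base_cds, 0.2, 0.0, seed=seed)
            errors.append(_ng86(base_cds, evolved).ks - 0.2)
        assert max(abs(e) for e in errors) < 0.05

    def test_planted_ks_correlates_with_estimate(self, base_cds):
        """Pearson r > 0.95 between planted and estimated Ks over 30 pairs."""
        rng = np.random.default_rng(7)
        planted, estimated = [], []
        for i in range(30):
            ks = float(rng.uniform(0.05, 0.9))
            evolved = evolve_cds(base_cds, ks, 0.1 * ks, seed=1000 + i)
            result = _ng86(base_cds, evolved)
            planted.append(ks)
            estimated.append(result.ks)
        r = scistats.pearsonr(planted, estimated).statistic
        assert r > 0.95

    def test_negative_target_rejected(self, base_cds):
        with pytest.raises(ValueError):
            evolve_cds(base_cds, -0.1, 0.0, seed=1)


class TestGenerateGenome:
    def test_same_seed_identical_bundles(self, small_config, small_bundle):
        again = synthetic.generate_genome(small_config)
        assert small_bundle.equals(again)

    def test_planted_tandem_array_adjacency(self, small_bundle):
        truth = small_bundle.truth
        members = truth.index[truth.tandem_array == "array01"]
        assert len(members) == 3
        order = small_bundle.gene_order()["chr1"]
        ranks = sorted(order.index(g) for g in members)
        assert ranks[2] - ranks[0] == 2  # consecutive gene ranks, gap 0

    def test_default_candidate_counts(self, default_bundle):
        truth = default_bundle.truth
        assert (truth.kind == "family").sum() == 189
        assert (truth.kind == "decoy").sum() == 17
        assert ((truth.kind == "family") | (truth.kind == "decoy")).sum() == 206

    def test_family_cds_translate_cleanly(self, small_bundle):
        for gene in small_bundle.gene_models:
            assert len(gene.cds) % 3 == 0
            translate_cds(gene.cds)  # decoys included: they translate too

    def test_truth_covers_every_gene_once(self, small_bundle):
        gene_ids = {g.gene_id for g in small_bundle.gene_models}
        assert set(small_bundle.truth.index) == gene_ids
        assert small_bundle.truth.index.is_unique

    def test_exons_within_bounds_and_sorted(self, small_bundle):
        for gene in small_bundle.gene_models:
            length = len(small_bundle.chromosome_sequences[gene.chromosome])
            assert 0 <= gene.start < gene.end <= length
            flat = [x for span in gene.exons for x in span]
            assert flat == sorted(flat)

    def test_cds_matches_chromosome_extraction(self, small_bundle):
        for gene in small_bundle.gene_models:
            chrom = small_bundle.chromosome_sequences[gene.chromosome]
            assert gene.extract_cds(chrom) == gene.cds

    def test_infeasible_layout_raises_sizing_error(self):
        config = GeneratorConfig(
            n_chromosomes=1, chromosome_length=2_000, n_background_genes=0,
            subfamily_plan={"AAP": 4}, tandem_arrays=(), collinear_blocks=(),
            decoy_truncated=0, seed=1)
        with pytest.raises(ValueError, match="fit"):
            synthetic.generate_genome(config)

    def test_invalid_target_ks_rejected(self):
        config = GeneratorConfig(
            collinear_blocks=(("chr1", "chr2", 3, 2.5),))
        with pytest.raises(ValueError, match="target_ks"):
            synthetic.generate_genome(config)


class TestGenerateExpression:
    def test_silent_genes_below_threshold_everywhere(self, default_bundle):
        truth = default_bundle.truth
        silent = truth.index[truth.archetype == "silent"]
        assert len(silent) == 18
        lengths = {g.gene_id: len(g.cds) for g in default_bundle.gene_models}
        for gene in silent:
            rpkm = (default_bundle.counts.loc[gene]
                    / (lengths[gene] / 1e3)
                    / (default_bundle.library_sizes / 1e6))
            assert (rpkm < 1.0).all()

    def test_pair_type_two_noise_free_ratio(self, default_bundle):
        # archetype means are applied before noise: planted type-II pairs
        # differ by a factor 4 per tissue, so the observed log2 ratio
        # concentrates around 2
        truth = default_bundle.truth
        type2 = truth.index[truth.archetype == "pair-type-II"]
        ratios = []
        for pair_id in truth.loc[type2, "pair_id"].unique():
            a, b = sorted(truth.index[truth.pair_id == pair_id])
            ratio = np.log2(
                (default_bundle.counts.loc[b] + 1) / (default_bundle.counts.loc[a] + 1))
            ratios.append(np.median(ratio))
        assert np.median(ratios) == pytest.approx(2.0, abs=0.4)

    def test_same_seed_identical_counts(self, default_bundle):
        counts, libs = synthetic.generate_expression(
            default_bundle, seed=default_bundle.config.seed)
        assert counts.equals(default_bundle.counts)
        assert libs.equals(default_bundle.library_sizes)

    def test_unknown_archetype_rejected(self, small_bundle):
        import dataclasses

        plan = dict(small_bundle.config.expression_plan)
        plan[next(iter(plan))] = "wobbly"
        broken = dataclasses.replace(small_bundle.config, expression_plan=plan)
        bundle = dataclasses.replace(small_bundle, config=broken)
        with pytest.raises(ValueError, match="wobbly"):
            synthetic.generate_expression(bundle, seed=0)


class TestBundleIO:
    def test_round_trip_identity(self, small_bundle, tmp_path):
        synthetic.write_bundle(small_bundle, tmp_path)
        again = synthetic.read_bundle(tmp_path)
        assert small_bundle.equals(again)

    def test_write_is_deterministic(self, small_bundle, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthetic.write_bundle(small_bundle, d1)
        synthetic.write_bundle(small_bundle, d2)
        for path in sorted(d1.iterdir()):
            assert path.read_bytes() == (d2 / path.name).read_bytes()

    def test_minus_strand_cds_is_reverse_complement_of_exons(
            self, small_bundle, tmp_path):
        synthetic.write_bundle(small_bundle, tmp_path)
        again = synthetic.read_bundle(tmp_path)
        minus = [g for g in again.gene_models if g.strand == "-"]
        assert minus, "expected at least one minus-strand gene"
        for gene in minus[:5]:
            chrom = again.chromosome_sequences[gene.chromosome]
            assembled = "".join(chrom[s:e] for s, e in gene.exons)
            assert reverse_complement(assembled) == gene.cds

    def test_empty_tissue_list_writes_header_only_counts(self, tmp_path):
        config = GeneratorConfig(
            n_chromosomes=1, chromosome_length=60_000, n_background_genes=4,
            subfamily_plan={"AAP": 3}, tandem_arrays=(), collinear_blocks=(),
            decoy_truncated=0, tissues=(), seed=3)
        bundle = synthetic.generate_genome(config)
        synthetic.write_bundle(bundle, tmp_path)
        lines = (tmp_path / "counts.tsv").read_text().splitlines()
        assert lines == ["gene_id"]
        again = synthetic.read_bundle(tmp_path)
        assert bundle.equals(again)
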