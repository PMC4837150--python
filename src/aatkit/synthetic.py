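"""Synthetic genome bundle generator with planted family structure.

Emits a toy multi-chromosome genome in which every downstream stage of the
survey has ground truth: family genes carrying a diagnostic domain, planted
tandem arrays, planted collinear duplicate blocks with controlled synonymous
divergence, truncated-domain decoys, non-family background genes, and an
11-tissue count matrix with planted expression archetypes.

Design of the planted homology structure: each subfamily derives from a
random founder protein that carries its group's diagnostic domain (kept
nearly intact across members) and a subfamily-specific signature segment;
outside those conserved segments members are heavily diverged, so that only
genuinely duplicated copies (tandem-array members and collinear-block anchor
pairs, generated by codon-level evolution at a controlled Ks) exceed the
homolog identity threshold. That makes the planted arrays and blocks exactly
the homology structure a detector should recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kaks
from .identify import AMINO_ACIDS
from .models import GeneModel, reverse_complement

DEFAULT_TISSUES = (
    "RT", "hypocotyl", "cotyledon", "callus", "SAM6d", "SAM17d", "SAM38d",
    "AM", "IBM", "IAM", "OF",
)

#: planted subfamily sizes; the totals follow the published family survey
#: (189 members, a single-member TTP clade, AAP the largest subfamily)
DEFAULT_SUBFAMILY_PLAN = {
    "AAP": 35, "LHT": 22, "ProT": 6, "GAT": 19, "AUX": 16, "ANT": 8,
    "ATLa": 16, "ATLb": 30, "TTP": 1, "CAT": 19, "ACT": 7, "PHS": 10,
}

DEFAULT_TANDEM_ARRAYS = (
    ("chr1", 2, 0), ("chr2", 2, 0), ("chr3", 2, 1), ("chr4", 2, 0),
    ("chr5", 5, 0), ("chr1", 6, 0), ("chr2", 6, 1), ("chr3", 11, 0),
)

DEFAULT_COLLINEAR_BLOCKS = (
    ("chr1", "chr2", 5, 0.08), ("chr2", "chr3", 5, 0.12),
    ("chr3", "chr4", 5, 0.18), ("chr4", "chr5", 5, 0.25),
    ("chr1", "chr3", 5, 0.35), ("chr2", "chr4", 5, 0.45),
)

DOMAIN_LENGTH = 60
SIGNATURE_LENGTH = 30
PROTEIN_LENGTH = 300
DECOY_DOMAIN_FRACTION = 0.4
TANDEM_KS = (0.03, 0.12)
KA_KS_RATIO = 0.2
MEMBER_BACKGROUND_KEEP = 0.10
CONSERVED_KEEP = 0.95
NOISE_SIGMA = 0.25  # log-normal multiplicative count noise
DETECTION_RPKM = 1.0
INTERGENIC_BP = 300

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in kaks.SENSE_CODONS:
    _CODONS_BY_AA.setdefault(kaks.CODON_TO_AA[_codon], []).append(_codon)


@dataclass(frozen=True)
class GeneratorConfig:
    n_chromosomes: int = 5
    chromosome_length: int = 400_000
    n_background_genes: int = 200
    subfamily_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBFAMILY_PLAN))
    tandem_arrays: tuple = DEFAULT_TANDEM_ARRAYS
    collinear_blocks: tuple = DEFAULT_COLLINEAR_BLOCKS
    decoy_truncated: int = 17
    tissues: tuple = DEFAULT_TISSUES
    expression_plan: dict[str, str] | None = None
    library_size: float = 5e6
    seed: int = 17

    @property
    def n_family_genes(self) -> int:
        return sum(self.subfamily_plan.values())

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if min([self.n_background_genes, self.decoy_truncated,
                *self.subfamily_plan.values()], default=0) < 0:
            raise ValueError("counts must be >= 0")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for chrom, size, gap in self.tandem_arrays:
            if chrom not in chroms or size < 2 or gap < 0:
                raise ValueError(f"bad tandem array ({chrom}, {size}, {gap})")
        for src, tgt, n_anchors, target_ks in self.collinear_blocks:
            if src not in chroms or tgt not in chroms or n_anchors < 1:
                raise ValueError(f"bad collinear block ({src}, {tgt}, {n_anchors})")
            if not 0.0 <= target_ks <= 1.5:
                raise ValueError(f"target_ks {target_ks} outside [0, 1.5]")


@dataclass
class SyntheticGenomeBundle:
    config: GeneratorConfig
    chromosome_sequences: dict[str, str]
    gene_models: list[GeneModel]
    truth: pd.DataFrame  # indexed by gene_id
    reference_proteins: dict[str, tuple[str, str]]  # ref id -> (seq, subfamily)
    domain_profiles: dict[str, list[str]]  # domain id -> aligned seed set
    counts: pd.DataFrame
    library_sizes: pd.Series

    @property
    def proteins(self) -> dict[str, str]:
        return {g.gene_id: translate_cds(g.cds) for g in self.gene_models}

    @property
    def cds(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.gene_models}

    def gene_order(self) -> dict[str, list[str]]:
        order: dict[str, list[tuple[int, str]]] = {}
        for gene in self.gene_models:
            order.setdefault(gene.chromosome, []).append((gene.start, gene.gene_id))
        return {c: [g for _, g in sorted(v)] for c, v in sorted(order.items())}

    def equals(self, other: "SyntheticGenomeBundle") -> bool:
        return (
            self.config == other.config
            and self.chromosome_sequences == other.chromosome_sequences
            and self.gene_models == other.gene_models
            and self.truth.equals(other.truth)
            and self.reference_proteins == other.reference_proteins
            and self.domain_profiles == other.domain_profiles
            and self.counts.equals(other.counts)
            and self.library_sizes.equals(other.library_sizes)
        )


def translate_cds(cds: str) -> str:
    protein = []
    for i in range(0, len(cds), 3):
        aa = kaks.translate_codon(cds[i : i + 3])
        if aa == "*":
            if i == len(cds) - 3:
                break
            raise ValueError(f"internal stop codon at {i}")
        protein.append(aa)
    return "".join(protein)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def _mutate_protein(protein: str, keep: np.ndarray, rng: np.random.Generator) -> str:
    """Per-position resampling: position i kept with probability keep[i]."""
    out = []
    for aa, p_keep in zip(protein, keep):
        if rng.random() < p_keep:
            out.append(aa)
        else:
            out.append(AMINO_ACIDS[rng.integers(0, 20)])
    return "".join(out)


def evolve_cds(cds: str, target_ks: float, target_ka: float, seed: int) -> str:
    """Mutated copy of a CDS with planted synonymous/nonsynonymous divergence.

    Substitution events are placed one at a time: pick a codon, a position and
    a replacement nucleotide uniformly; accept the event only if its site
    class (synonymous vs nonsynonymous, judged on the current codon) still has
    quota and it creates no stop codon. Event quotas are ``round(target *
    sites)`` with NG86 site fractions of the input sequence, so the planted
    divergence is on the corrected (multiple-hit) scale that the NG86
    estimator reports.
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("targets must be >= 0")
    protein = translate_cds(cds)  # validates the input
    n_codons = len(cds) // 3
    syn_sites = sum(kaks.codon_sites(cds[3 * i : 3 * i + 3])[0] for i in range(n_codons))
    nonsyn_sites = 3.0 * n_codons - syn_sites
    needed_syn = int(round(target_ks * syn_sites))
    needed_nonsyn = int(round(target_ka * nonsyn_sites))
    rng = np.random.default_rng(seed)
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    budget = 50 * max(1, needed_syn + needed_nonsyn)
    attempts = 0
    while needed_syn + needed_nonsyn > 0:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not place substitutions: {needed_syn} syn / "
                f"{needed_nonsyn} nonsyn remaining after {budget} attempts"
            )
        idx = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        nt = kaks.NUCLEOTIDES[rng.integers(0, 4)]
        codon = codons[idx]
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt in kaks.STOP_CODONS:
            continue
        synonymous = kaks.CODON_TO_AA[alt] == kaks.CODON_TO_AA[codon]
        if synonymous and needed_syn > 0:
            codons[idx] = alt
            needed_syn -= 1
        elif not synonymous and needed_nonsyn > 0:
            codons[idx] = alt
            needed_nonsyn -= 1
    evolved = "".join(codons)
    if target_ka == 0 and translate_cds(evolved) != protein:
        raise AssertionError("synonymous-only evolution changed the protein")
    return evolved


# ---------------------------------------------------------------------------
# generation


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def default_expression_plan(pair_roles: list[str], single_roles: list[str],
                            tissues: tuple) -> dict[str, str]:
    """Archetype per gene-role: pairs cycle the three divergence types;
    singles get 18 silent, then tissue-cycling preferential, then constitutive."""
    plan: dict[str, str] = {}
    pair_types = ["pair-type-I", "pair-type-II", "pair-type-III"]
    for i, role in enumerate(pair_roles):
        plan[role] = pair_types[i % 3]
    n_silent = min(18, len(single_roles))
    n_pref = min(45, max(0, len(single_roles) - n_silent)) if tissues else 0
    for i, role in enumerate(single_roles):
        if i < n_silent:
            plan[role] = "silent"
        elif i < n_silent + n_pref:
            plan[role] = f"preferential:{tissues[i % len(tissues)]}"
        else:
            plan[role] = "constitutive"
    return plan


def generate_genome(config: GeneratorConfig) -> SyntheticGenomeBundle:
    """Full bundle generation; same config (and seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    group_of = {
        "AAP": "AAAP", "LHT": "AAAP", "ProT": "AAAP", "GAT": "AAAP",
        "AUX": "AAAP", "ANT": "AAAP", "ATLa": "AAAP", "ATLb": "AAAP",
        "TTP": "AAAP", "CAT": "APC", "ACT": "APC", "PHS": "APC",
    }

    # diagnostic domains: one per family group, shared by its subfamilies
    domain_consensus = {
        "ATD1": _random_protein(rng, DOMAIN_LENGTH),  # amino-acid/auxin permease type
        "ATD2": _random_protein(rng, DOMAIN_LENGTH),  # amino-acid-polyamine-choline type
    }
    domain_profiles: dict[str, list[str]] = {}
    for domain_id, consensus in domain_consensus.items():
        seeds = []
        for _ in range(8):
            seq = list(consensus)
            for pos in rng.choice(DOMAIN_LENGTH, size=3, replace=False):
                seq[pos] = AMINO_ACIDS[rng.integers(0, 20)]
            seeds.append("".join(seq))
        domain_profiles[domain_id] = seeds

    # founders: background + domain + subfamily signature, fixed layout
    founders: dict[str, str] = {}
    keep_profile: dict[str, np.ndarray] = {}
    for subfamily in config.subfamily_plan:
        group = group_of.get(subfamily, "AAAP")
        domain = domain_consensus["ATD1" if group == "AAAP" else "ATD2"]
        signature = _random_protein(rng, SIGNATURE_LENGTH)
        domain_start = int(rng.integers(40, 120))
        signature_start = domain_start + DOMAIN_LENGTH + int(rng.integers(20, 60))
        n_bg_tail = PROTEIN_LENGTH - signature_start - SIGNATURE_LENGTH
        founder = (
            _random_protein(rng, domain_start) + domain
            + _random_protein(rng, signature_start - domain_start - DOMAIN_LENGTH)
            + signature + _random_protein(rng, n_bg_tail)
        )
        keep = np.full(PROTEIN_LENGTH, MEMBER_BACKGROUND_KEEP)
        keep[domain_start : domain_start + DOMAIN_LENGTH] = CONSERVED_KEEP
        keep[signature_start : signature_start + SIGNATURE_LENGTH] = CONSERVED_KEEP
        founders[subfamily] = founder
        keep_profile[subfamily] = keep

    # labeled reference exemplars: the founder plus two light variants each
    reference_proteins: dict[str, tuple[str, str]] = {}
    for subfamily, founder in founders.items():
        reference_proteins[f"ref_{subfamily}_1"] = (founder, subfamily)
        light = np.where(keep_profile[subfamily] >= CONSERVED_KEEP, 0.98, 0.90)
        for i in (2, 3):
            reference_proteins[f"ref_{subfamily}_{i}"] = (
                _mutate_protein(founder, light, rng), subfamily)

    def new_member(subfamily: str) -> str:
        protein = _mutate_protein(founders[subfamily], keep_profile[subfamily], rng)
        return _reverse_translate(protein, rng)

    remaining = dict(config.subfamily_plan)

    def take(n: int) -> str:
        candidates = [s for s, r in sorted(remaining.items()) if r >= n]
        if not candidates:
            raise ValueError(f"no subfamily has {n} unassigned members left")
        subfamily = max(candidates, key=lambda s: (remaining[s], s))
        remaining[subfamily] -= n
        return subfamily

    gene_seq = iter(range(1, 10**6))
    truth_rows: list[dict] = []
    cds_of: dict[str, str] = {}
    placement: dict[str, list[str]] = {c: [] for c in chroms}
    bg_pool = [f"bg{i + 1:03d}" for i in range(config.n_background_genes)]
    bg_iter = iter(bg_pool)

    def new_gene_id() -> str:
        return f"g{next(gene_seq):04d}"

    def add_truth(gene_id: str, kind: str, subfamily: str | None = None,
                  tandem_array: str | None = None, collinear_block: str | None = None,
                  pair_id: str | None = None, role: str | None = None) -> None:
        truth_rows.append({
            "gene_id": gene_id, "kind": kind, "subfamily": subfamily,
            "tandem_array": tandem_array, "collinear_block": collinear_block,
            "pair_id": pair_id, "decoy": kind == "decoy", "role": role,
        })

    pair_roles: list[str] = []
    # collinear blocks: anchor pairs evolved at the block's target Ks
    for b_idx, (src, tgt, n_anchors, target_ks) in enumerate(config.collinear_blocks):
        block_id = f"block{b_idx + 1:02d}"
        for a_idx in range(n_anchors):
            subfamily = take(2)
            gene_a, gene_b = new_gene_id(), new_gene_id()
            cds_a = new_member(subfamily)
            cds_b = evolve_cds(cds_a, target_ks, KA_KS_RATIO * target_ks,
                               seed=_spawn_seed(rng))
            cds_of[gene_a], cds_of[gene_b] = cds_a, cds_b
            placement[src].append(gene_a)
            placement[tgt].append(gene_b)
            pair_id = f"{block_id}_p{a_idx + 1}"
            role = f"pair:{len(pair_roles)}"
            pair_roles.append(role)
            add_truth(gene_a, "family", subfamily, collinear_block=block_id,
                      pair_id=pair_id, role=role)
            add_truth(gene_b, "family", subfamily, collinear_block=block_id,
                      pair_id=pair_id, role=role)

    # tandem arrays: members evolved from one seed copy at low Ks
    single_roles: list[str] = []
    for t_idx, (chrom, size, gap) in enumerate(config.tandem_arrays):
        array_id = f"array{t_idx + 1:02d}"
        subfamily = take(size)
        seed_cds = new_member(subfamily)
        member_cds = [seed_cds] + [
            evolve_cds(
                seed_cds,
                float(rng.uniform(*TANDEM_KS)),
                KA_KS_RATIO * float(rng.uniform(*TANDEM_KS)),
                seed=_spawn_seed(rng),
            )
            for _ in range(size - 1)
        ]
        for m_idx, cds in enumerate(member_cds):
            gene_id = new_gene_id()
            cds_of[gene_id] = cds
            placement[chrom].append(gene_id)
            role = f"single:{len(single_roles)}"
            single_roles.append(role)
            add_truth(gene_id, "family", subfamily, tandem_array=array_id, role=role)
            if m_idx < size - 1:
                for _ in range(gap):
                    try:
                        placement[chrom].append(next(bg_iter))
                    except StopIteration:
                        raise ValueError(
                            "not enough background genes for tandem-array gaps"
                        ) from None

    # remaining family members as singletons, round-robin over chromosomes
    singles: list[tuple[str, str]] = []
    for subfamily in sorted(remaining):
        for _ in range(remaining[subfamily]):
            singles.append((new_gene_id(), subfamily))
    remaining = {s: 0 for s in remaining}
    for i, (gene_id, subfamily) in enumerate(singles):
        cds_of[gene_id] = new_member(subfamily)
        placement[chroms[i % len(chroms)]].append(gene_id)
        role = f"single:{len(single_roles)}"
        single_roles.append(role)
        add_truth(gene_id, "family", subfamily, role=role)

    # truncated-domain decoys: background protein ending in a partial domain
    decoy_length = int(DECOY_DOMAIN_FRACTION * DOMAIN_LENGTH)
    for d_idx in range(config.decoy_truncated):
        gene_id = f"d{d_idx + 1:03d}"
        protein = (
            _random_protein(rng, PROTEIN_LENGTH - decoy_length)
            + domain_consensus["ATD1"][:decoy_length]
        )
        cds_of[gene_id] = _reverse_translate(protein, rng)
        placement[chroms[d_idx % len(chroms)]].append(gene_id)
        add_truth(gene_id, "decoy")

    # background genes not consumed as array spacers
    for i, bg_id in enumerate(bg_iter):
        protein = _random_protein(rng, int(rng.integers(120, 250)))
        cds_of[bg_id] = _reverse_translate(protein, rng)
        placement[chroms[i % len(chroms)]].append(bg_id)
        add_truth(bg_id, "background")
    for bg_id in bg_pool:
        if bg_id not in cds_of:  # consumed as an array spacer
            protein = _random_protein(rng, int(rng.integers(120, 250)))
            cds_of[bg_id] = _reverse_translate(protein, rng)
            add_truth(bg_id, "background")

    truth = pd.DataFrame(truth_rows).set_index("gene_id").sort_index()

    # gene models and chromosome sequences
    gene_models: list[GeneModel] = []
    chromosome_sequences: dict[str, str] = {}
    nts = np.array(list("ACGT"))
    for chrom in chroms:
        sequence = rng.choice(nts, size=config.chromosome_length)
        cursor = INTERGENIC_BP
        for gene_id in placement[chrom]:
            cds = cds_of[gene_id]
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 9))
            cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                                     replace=False)) if n_exons > 1 else []
            pieces = np.split(np.arange(len(cds)), cuts)
            genomic = cds if strand == "+" else reverse_complement(cds)
            # exon lengths along the chromosome follow the genomic orientation
            lengths = [len(p) for p in pieces]
            if strand == "-":
                lengths = lengths[::-1]
            introns = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]
            span = sum(lengths) + sum(introns)
            if cursor + span + INTERGENIC_BP > config.chromosome_length:
                raise ValueError(
                    f"genes do not fit on {chrom}: need > {cursor + span} bp "
                    f"of {config.chromosome_length}"
                )
            exons = []
            pos = cursor
            offset = 0
            for e_idx, length in enumerate(lengths):
                exons.append((pos, pos + length))
                sequence[pos : pos + length] = list(genomic[offset : offset + length])
                offset += length
                pos += length
                if e_idx < len(introns):
                    pos += introns[e_idx]
            gene_models.append(GeneModel(
                gene_id=gene_id, chromosome=chrom, start=cursor, end=pos,
                strand=strand, exons=tuple(exons), cds=cds,
            ))
            cursor = pos + INTERGENIC_BP
        chromosome_sequences[chrom] = "".join(sequence)

    gene_models.sort(key=lambda g: (g.chromosome, g.start))

    plan = config.expression_plan or default_expression_plan(
        pair_roles, single_roles, config.tissues)
    config = dataclasses.replace(config, expression_plan=plan)

    bundle = SyntheticGenomeBundle(
        config=config,
        chromosome_sequences=chromosome_sequences,
        gene_models=gene_models,
        truth=truth,
        reference_proteins=reference_proteins,
        domain_profiles=domain_profiles,
        counts=pd.DataFrame(),
        library_sizes=pd.Series(dtype=float),
    )
    bundle.counts, bundle.library_sizes = generate_expression(bundle, seed=config.seed)
    bundle.truth = bundle.truth.assign(
        archetype=[_archetype_for(bundle, g) for g in bundle.truth.index])
    return bundle


def _archetype_for(bundle: SyntheticGenomeBundle, gene_id: str) -> str:
    role = bundle.truth.loc[gene_id, "role"]
    plan = bundle.config.expression_plan or {}
    if role is not None and role in plan:
        return plan[role]
    return "constitutive"


def generate_expression(bundle: SyntheticGenomeBundle,
                        seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Integer count matrix and per-tissue library sizes for a bundle.

    Counts are drawn around archetype RPKM means with log-normal
    multiplicative noise (sigma 0.25) and rounded; silent genes stay below
    the detection threshold in every tissue by construction.
    """
    config = bundle.config
    tissues = list(config.tissues)
    if not tissues:
        return (
            pd.DataFrame(index=pd.Index([], name="gene_id", dtype=object)),
            pd.Series(dtype=float, name="mapped_reads"),
        )
    rng = np.random.default_rng(seed + 1)
    library_sizes = pd.Series(
        np.round(config.library_size * rng.uniform(0.9, 1.1, size=len(tissues))),
        index=tissues, name="mapped_reads",
    )
    plan = config.expression_plan or {}
    n_tissues = len(tissues)

    means: dict[str, np.ndarray] = {}
    pair_shapes: dict[str, np.ndarray] = {}
    for gene_id in bundle.truth.index:
        role = bundle.truth.loc[gene_id, "role"]
        archetype = plan.get(role, "constitutive") if role else "constitutive"
        if archetype == "constitutive":
            level = 2.0 ** rng.uniform(3, 6)
            means[gene_id] = np.full(n_tissues, level)
        elif archetype == "silent":
            means[gene_id] = np.full(n_tissues, 0.05)
        elif archetype.startswith("preferential:"):
            tissue = archetype.split(":", 1)[1]
            if tissue not in tissues:
                raise ValueError(f"unknown tissue {tissue!r} in archetype")
            base = 2.0 ** rng.uniform(1, 2.5)
            profile = np.full(n_tissues, base)
            profile[tissues.index(tissue)] = base * 12.0
            means[gene_id] = profile
        elif archetype.startswith("pair-type-"):
            pair_id = bundle.truth.loc[gene_id, "pair_id"]
            if pair_id not in pair_shapes:
                # per-pair tissue pattern standardized to a fixed log2 dynamic
                # range so every planted pair carries an identifiable pattern
                raw = rng.normal(0.0, 1.0, n_tissues)
                raw = (raw - raw.mean()) / raw.std()
                pair_shapes[pair_id] = rng.uniform(2, 5) + 1.5 * raw
            shape = pair_shapes[pair_id]
            members = sorted(bundle.truth.index[bundle.truth["pair_id"] == pair_id])
            is_second = gene_id == members[-1]
            kind = archetype.removeprefix("pair-type-")
            if kind == "I":
                log2_profile = shape
            elif kind == "II":
                log2_profile = shape + (2.0 if is_second else 0.0)
            elif kind == "III":
                log2_profile = shape if not is_second else (2 * shape.mean() - shape)
            else:
                raise ValueError(f"unknown archetype {archetype!r}")
            means[gene_id] = 2.0 ** log2_profile
        else:
            raise ValueError(f"unknown archetype {archetype!r}")

    lengths = {g.gene_id: len(g.cds) for g in bundle.gene_models}
    counts = np.zeros((len(bundle.truth.index), n_tissues), dtype=np.int64)
    gene_ids = list(bundle.truth.index)
    libs = library_sizes.to_numpy()
    for row, gene_id in enumerate(gene_ids):
        base = means[gene_id] * (lengths[gene_id] / 1e3) * (libs / 1e6)
        noise = np.exp(rng.normal(0.0, NOISE_SIGMA, size=n_tissues))
        counts[row] = np.round(base * noise).astype(np.int64)
    return (
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=tissues),
        library_sizes,
    )


# ---------------------------------------------------------------------------
# bundle I/O (FASTA wrapped at 60 columns, GFF3 1-based inclusive, TSV)


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with path.open("w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.description, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_bundle(bundle: SyntheticGenomeBundle, directory: str | Path) -> None:
    """Persist the bundle; ``read_bundle`` on the directory reproduces it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_fasta(directory / "chromosomes.fasta",
                 sorted(bundle.chromosome_sequences.items()))
    _write_fasta(directory / "cds.fasta",
                 [(g.gene_id, g.cds) for g in bundle.gene_models])
    _write_fasta(directory / "proteins.fasta",
                 [(g.gene_id, translate_cds(g.cds)) for g in bundle.gene_models])
    _write_fasta(directory / "references.fasta",
                 [(f"{ref_id} subfamily={label}", seq)
                  for ref_id, (seq, label) in sorted(bundle.reference_proteins.items())])
    for domain_id, seeds in sorted(bundle.domain_profiles.items()):
        _write_fasta(directory / f"domain_{domain_id}.aln.fasta",
                     [(f"{domain_id}_seed{i + 1}", seq) for i, seq in enumerate(seeds)])

    with (directory / "genes.gff3").open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in bundle.gene_models:
            attrs = f"ID={gene.gene_id}"
            fh.write("\t".join([
                gene.chromosome, "aatkit", "gene", str(gene.start + 1),
                str(gene.end), ".", gene.strand, ".", attrs]) + "\n")
            mrna = f"{gene.gene_id}.t1"
            fh.write("\t".join([
                gene.chromosome, "aatkit", "mRNA", str(gene.start + 1),
                str(gene.end), ".", gene.strand, ".",
                f"ID={mrna};Parent={gene.gene_id}"]) + "\n")
            for s, e in gene.exons:
                fh.write("\t".join([
                    gene.chromosome, "aatkit", "exon", str(s + 1), str(e),
                    ".", gene.strand, ".", f"Parent={mrna}"]) + "\n")
            # CDS phase per segment, accumulated in transcription order
            ordered = gene.exons if gene.strand == "+" else gene.exons[::-1]
            phases = {}
            consumed = 0
            for s, e in ordered:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s
            for s, e in gene.exons:
                fh.write("\t".join([
                    gene.chromosome, "aatkit", "CDS", str(s + 1), str(e),
                    ".", gene.strand, str(phases[(s, e)]),
                    f"Parent={mrna}"]) + "\n")

    bundle.truth.to_csv(directory / "truth.tsv", sep="\t")
    bundle.counts.to_csv(directory / "counts.tsv", sep="\t")
    bundle.library_sizes.rename_axis("tissue").to_csv(
        directory / "library_sizes.tsv", sep="\t")
    config = dataclasses.asdict(bundle.config)
    config["tandem_arrays"] = [list(t) for t in config["tandem_arrays"]]
    config["collinear_blocks"] = [list(t) for t in config["collinear_blocks"]]
    config["tissues"] = list(config["tissues"])
    (directory / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True))


def read_gff3(path: str | Path, cds_sequences: dict[str, str] | None = None,
              ) -> list[GeneModel]:
    """Parse a GFF3 file into gene models (1-based inclusive -> half-open)."""
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, kind, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(item.split("=", 1) for item in attrs.split(";") if item)
            if kind == "gene":
                genes[fields["ID"]] = {
                    "chromosome": chrom, "start": int(start) - 1, "end": int(end),
                    "strand": strand, "exons": [],
                }
            elif kind == "mRNA":
                mrna_parent[fields["ID"]] = fields["Parent"]
            elif kind == "exon":
                gene_id = mrna_parent[fields["Parent"]]
                genes[gene_id]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gene_id, info in genes.items():
        exons = tuple(sorted(info.pop("exons")))
        cds = cds_sequences.get(gene_id, "") if cds_sequences else ""
        models.append(GeneModel(gene_id=gene_id, exons=exons, cds=cds, **info))
    models.sort(key=lambda g: (g.chromosome, g.start))
    return models


def read_bundle(directory: str | Path) -> SyntheticGenomeBundle:
    directory = Path(directory)
    config_raw = json.loads((directory / "config.json").read_text())
    config_raw["tandem_arrays"] = tuple(tuple(t) for t in config_raw["tandem_arrays"])
    config_raw["collinear_blocks"] = tuple(
        tuple(t) for t in config_raw["collinear_blocks"])
    config_raw["tissues"] = tuple(config_raw["tissues"])
    config = GeneratorConfig(**config_raw)

    chromosome_sequences = dict(_read_fasta(directory / "chromosomes.fasta"))
    cds_sequences = dict(_read_fasta(directory / "cds.fasta"))
    gene_models = read_gff3(directory / "genes.gff3", cds_sequences)
    references = {}
    for description, seq in _read_fasta(directory / "references.fasta"):
        ref_id, *rest = description.split()
        label = dict(item.split("=", 1) for item in rest)["subfamily"]
        references[ref_id] = (seq, label)
    domain_profiles: dict[str, list[str]] = {}
    for path in sorted(directory.glob("domain_*.aln.fasta")):
        domain_id = path.name[len("domain_") : -len(".aln.fasta")]
        domain_profiles[domain_id] = [seq for _, seq in _read_fasta(path)]
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col="gene_id")
    for column in truth.columns:  # all-NA columns must stay object-typed
        if column != "decoy":
            truth[column] = truth[column].astype(object)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="gene_id")
    library_sizes = pd.read_csv(
        directory / "library_sizes.tsv", sep="\t", index_col="tissue",
    )["mapped_reads"].astype(float)
    return SyntheticGenomeBundle(
        config=config,
        chromosome_sequences=chromosome_sequences,
        gene_models=gene_models,
        truth=truth,
        reference_proteins=references,
        domain_profiles=domain_profiles,
        counts=counts,
        library_sizes=library_sizes,
    )
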