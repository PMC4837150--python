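# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind `aatkit`, in the order the pipeline runs them.

## Domain-profile identification

Family membership is decided by scanning proteins with per-column log-odds
profiles (bits against a uniform 1/20 background, per-cell pseudocount 0.1,
columns with > 50% gaps dropped) built from aligned seed sets of the two
diagnostic transporter domains. This is a deliberate simplification of a
profile HMM: no insert/delete states, but the same decision surface — a
score and a profile coverage per hit. Placements may overhang either
sequence end (coverage < 1), which is what detects fragmentary domains;
placements overlapping fewer than max(10, 25%) of the profile columns are
not scored, so that near-empty overlaps cannot dominate the null.

The score threshold is not hand-set: it is calibrated per profile as the
99th percentile of best-placement scores on 500 random uniform-composition
proteins (seeded). By construction roughly 1% of random sequences exceed
it, which is why a survey run typically reports a couple of background
candidates beyond the planted family — they carry partial hits and are then
rejected by the completeness filter. A candidate is accepted when at least
one hit covers ≥ 50% of a profile (`min_coverage`, configurable); rejected
candidates carry `short_or_incomplete_domain` or `no_hit`. Accepted genes
are named subfamily-prefix + rank, ranked by (chromosome, start), which
makes names reproducible across reruns.

## Protein features

Molecular weight is the sum of average residue masses plus one water, and
the isoelectric point is the root of the Bjellqvist net-charge model
(termini plus D, E, C, Y, H, K, R), both via biopython's ProtParam. The
library's own pI solver bisects only inside pH [4.05, 12], which clamps
strongly acidic peptides; we instead solve the same charge function by
Brent's method on [0, 14] (|charge| ≪ 1e-4 at the root). The pKa set is
pinned in the module to keep reported pI values reproducible.

Transmembrane spans use a sliding-window Kyte–Doolittle hydropathy mean
(window 19, threshold 1.6), merging runs separated by ≤ 5 residues and
keeping runs ≥ 15 residues. This is a transparent surrogate for HMM-based
TM predictors; it preserves the downstream contract (a per-protein span
count, possibly zero) but will not reproduce topology predictions on real
proteins. The packaged catalog of 20 conserved family motifs is matched by
exact-width Hamming scan with a mismatch budget of 10% of motif width
(rounded down); the catalog's stored widths are checked against sequence
lengths at load and any disagreement is an error, never silently corrected.

## Duplication analysis

Homologous pairs come from all-vs-all global alignment (Needleman–Wunsch,
BLOSUM62, gap open 10 / extend 0.5 in the convention where the first gapped
position pays the open penalty), retained at identity ≥ 0.4 and score ≥ 50.
Tandem arrays are connected components of pairs on one chromosome separated
by ≤ `max_gap` = 1 non-family genes — a strict reading of "same or
neighboring intergenic regions"; the parameter is configurable because no
canonical value exists. Collinear (WGD/segmental) blocks are extracted per
chromosome pair by a dynamic program maximizing anchor count under strict
rank monotonicity (same or inverted orientation) with consecutive rank gaps
≤ 25 and ≥ 3 anchors per block at this toy scale (5 is the conventional
full-genome value); blocks are taken greedily by descending length with
deterministic tie-breaks, and anchors of an emitted block are removed before
searching again. Pairs internal to one tandem array are masked before
chaining, as collinearity scanners conventionally do — otherwise an array of
n ≥ 3 near-identical neighbors chains into a spurious intra-chromosomal
"block". A gene in an array and a block is called `both`.

## Ka/Ks, dating, and selection

The Nei–Gojobori (1986) method is implemented in full: per-codon
synonymous-site fractions by enumerating the three single-nucleotide
neighbors of each position (changes to stop codons count as nonsynonymous,
so each codon contributes exactly 3 sites); observed differences averaged
over all minimal substitution pathways, excluding pathways that cross a
stop codon (if every pathway is blocked, the average falls back to all
pathways); Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p), with p ≥ 3/4
flagged saturated rather than raised. Codon alignments are built by
threading CDS through the pairwise protein alignment and dropping columns
with a gap or ambiguity. An independent brute-force oracle (recursive
pathway enumeration) validates the implementation to 1e-9 in the tests.

Duplication age is T = Ks / (2λ), with λ = 6.1 × 10⁻⁹ synonymous
substitutions per site per year (the standard legume clock), overridable per
run. Selection is purifying/neutral/positive as Ka/Ks is below/at/above 1
(neutral within 1e-9), undefined when Ks = 0. WGD-round assignment uses a
recent cutoff of 25 My — any value between the largest recent-pair date
(19.92 My) and the smallest excluded one (28.53 My) in the packaged
reference table yields the same 20/3 split — and an ancient/pre-WGD
boundary of 65 My bracketing the ~58–60 Mya event.

The packaged 23-pair reference table is regressed at 1% relative tolerance.
The published ratio and date columns were computed from unrounded Ka/Ks, so
recomputation from the printed three-decimal values deviates beyond 1% for
9 of 23 ratios; each such deviation is verified to lie inside the ±0.0005
rounding band of the printed inputs and is reported as rounding-induced. A
deviation not explicable by rounding fails the regression.

## Phylogeny and subfamily classification

Trees are neighbor-joining on p-distances (1 − alignment identity; not a
metric, and documented as such), with negative branch-length estimates
clamped to zero. Bootstrap support resamples the columns of each pairwise
alignment independently, rebuilds the distance matrix and tree, and scores
each bipartition of the main tree as the percentage of replicates
containing it — an approximation of the MSA bootstrap (no shared columns
across pairs) that is adequate for the support ranges used here. ML tree
search is deliberately out of scope; subfamily classification consumes only
distances, via a k = 3 nearest-reference majority vote (ties resolved
toward the closest reference, residual exact ties flagged ambiguous), so
the tree method does not affect the calls. k = 3 tolerates one mislabeled
reference.

## Expression

RPKM = count / (mRNA kb) / (mapped reads in millions). A gene is silent
when every tissue is below RPKM 1 (the published survey states "no
expression" without a threshold; RPKM < 1 is this package's pinned
surrogate), uniform when detected with max/min fold range < 2 (the
detection-adjusted minimum avoids division by near-zero), regulated
otherwise; tissues at ≥ 2× the runner-up are "preferred". Pair divergence
uses Pearson r on log2(RPKM + 0.1) and per-tissue log2 ratios: type I when
r ≥ 0.8 with |median ratio| < 1; type II when r ≥ 0.8, the ratio is
one-sided, and |median ratio| ≥ 1 (ties in individual tissues do not break
one-sidedness — the median already demands a real shift); type III
otherwise. A zero-variance profile leaves r undefined and the call falls
through to the magnitude rules. All cutoffs are config-pinned; the source
material defines the three types pictorially, with no numbers.

## Synthetic study conditions

The generator's defaults are the survey's study conditions. The subfamily
plan totals 189 members over the 12 subfamilies (AAP largest at 35, TTP a
single member), with 17 truncated-domain decoys (40% of the domain at the
C-terminus, below the 50% completeness cutoff) giving 206 candidates, plus
200 background genes on 5 chromosomes of 400 kb.

Planted homology is engineered so detection has an exact target: each
subfamily derives from a random founder protein (300 aa) carrying its
group's diagnostic domain (60 aa, kept at 95% identity across members) and
a 30-aa subfamily signature (also 95%), with all other positions resampled
at 90% probability per member. Ordinary co-members therefore share ~30–35%
identity — comfortably below the 0.4 homolog threshold — while genuine
duplicate copies, generated by codon-level evolution, sit near 90%. The 8
tandem arrays (sizes 2,2,2,2,5,6,6,11 = 36 genes, at Ks ~ U(0.03, 0.12))
and 6 collinear blocks (5 anchors each = 30 pairs = 60 genes, block Ks
0.08–0.45, Ka/Ks 0.2) are thus exactly the above-threshold homology
structure, and the truth table is an exact answer key.

`evolve_cds` plants divergence on the corrected scale: event quotas are
round(target × NG86 sites of the input), events are placed by picking a
codon, position and replacement uniformly, accepted only if the site class
still has quota and no stop codon arises (bounded at 50× the quota). Since
repeated hits at one site are allowed, the Jukes–Cantor correction of the
estimator recovers the planted rate; round-trip accuracy is ±0.05 at
Ks = 0.2 (500 codons) and the worst mean relative error over
Ks ∈ {0.1, 0.2, 0.4, 0.8} stays within ±15%.

Expression counts are drawn around archetype RPKM means with log-normal
multiplicative noise (σ = 0.25) and rounded; per-tissue library sizes are
~5 × 10⁶ reads (the real mapped-read totals behind the published RPKM are
unknown, so library size is a free generator parameter). Archetypes:
18 silent genes (mean RPKM 0.05 — integer rounding keeps every tissue below
detection), 45 tissue-preferential genes (12× spike over a low base),
constitutive genes (uniform mean, 8–64 RPKM), and 30 duplicate pairs
cycling types I/II/III (10 each). Pair patterns are standardized to a fixed
log2 dynamic range (SD 1.5) before the type transform so every planted pair
carries an identifiable pattern; type II scales one member 4×, type III
mirrors the pattern around its mean.

One consequence of σ = 0.25 worth stating: across 11 tissues the expected
max/min fold range of a flat-mean gene exceeds 2 about two-thirds of the
time, so most constitutive genes are *reported* as "regulated" by the
strict < 2-fold rule. The recovery scoring therefore checks constitutive
genes for their defining property — detected everywhere with no preferred
tissue — rather than for the literal `uniform` label; silent and
preferential genes are checked literally. The generator emulates planted
means plus independent log-normal noise; it does not emulate read-level
sampling, mapping bias, or correlated library effects, so passing recovery
tests demonstrate the classifiers' decision rules, not robustness to real
RNA-seq artifacts. Likewise the genome generator omits intergenic repeats,
UTRs and alternative splicing, and its gene structures (1–8 exons, introns
80–300 bp) are only bounded by, not matched to, real gene architecture.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed (default 17); a fixed
configuration reproduces byte-identical bundles, outputs and summary JSON.
The shipped defaults (406 genes, ~18k pairwise alignments for the
all-vs-all stage) run the full survey in well under a minute on one CPU;
the family-wide NJ bootstrap is opt-in (`--bootstrap`) because 100
replicates over 189 leaves dominate the runtime while the subfamily calls,
which are distance-based, do not need them.

## Known limitations

- The profile scan has no gap states; domains split by long insertions
  would score as truncated.
- p-distance NJ is a classification aid, not a substitute for ML phylogeny;
  branch lengths after negative-length clamping are not additive.
- NG86 assumes equal substitution rates; transition/transversion bias in
  real data inflates Ks relative to pathway-weighted estimators.
- The chromosome-level layout is synthetic; chromosome-distribution counts
  of the real survey are not a target of this artifact.
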