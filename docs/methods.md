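# Methods

## Data model

The unit of observation is an isoform-level expression table: TPM per
(gene, pAS) per sample, where each pAS is the 3′ end of one 3′-UTR
isoform. Samples are annotated with tissue, ordered developmental stage
and replicate. Genomic inputs are a genome FASTA, pAS point features and
stop-codon points in BED (0-based half-open; a pAS occupies exactly one
base, the cleavage position on the transcript strand), and optional
annotation tracks: miRNA sites, transposable elements (with a family
column), CLIP peaks, and a conservation bedGraph with a coding-sequence
mask.

### Coordinate and strand conventions

All intervals are 0-based half-open. Transcript orientation is derived
from the strand: on `-` strand genes "downstream" means decreasing
coordinate and sequences are reverse-complemented before any
sequence-level computation. Every statistic in the package is invariant
under reverse-complementing the genome and reflecting all annotations
(`simulate.mirror_dataset`); the test suite checks this bit-exactly.

## Usage quantification

- **PAU** (polyA usage): `100 × TPM_i / Σ_gene TPM` per sample. All
  PAUs of a gene are set to missing in samples where the gene total is
  below 0.1 TPM — ratios of near-zero counts are noise, not usage.
- **PPAU**: the PAU of the gene's rank-1 (most 5′) pAS. High PPAU means
  short-UTR dominance.
- **pAS classes**: genes with one site are SPA; in multi-site genes the
  5′-most is APA-proximal, the 3′-most APA-distal, anything between
  APA-middle.
- **Weighted 3′-UTR length**: `Σ L_i × PAU_i / 100` with `L_i` the
  stop-codon-to-pAS distance; a usage-weighted average isoform length.
  Long/short-UTR calls per tissue require the weighted length to exceed
  every other tissue (or a majority, configurable) by a 100 nt margin.
- **Usage entropy**: `−Σ (PAU_i/100) log2(PAU_i/100)` — 0 bits for a
  single used site, 1 bit for an even 2-site split, 2 bits for an even
  4-site split.
- **Tissue specificity**: `TS = max/mean` of gene TPM across tissues
  (1 = uniform, n = exclusive to one of n tissues). Expression strata:
  low ≤ 5 TPM, high ≥ 15 TPM.
- **ΔPPAU gate**: pairwise contrasts use `Δ = PPAU_a − PPAU_b` and call
  significance at |Δ| ≥ 20 percentage points. The gate is an amplitude
  criterion, deliberately scale-bound: replicate-mean PPAU noise in the
  intended data sizes is a few points, so 20 points separates real
  usage shifts from noise without any distributional assumption.
- **Sample clustering**: average-linkage hierarchical clustering on
  `1 − Pearson` distance over pairwise-complete genes, deterministic
  ordering, flat cut at a chosen k.

## Sequence features

The ±50 nt context of each pAS is extracted on the transcript strand
(out-of-genome positions padded with N). The polyA signal is the best
hexamer in the upstream 50 nt from an 18-hexamer catalog with AATAAA
and ATTAAA first; catalog order breaks ties, and among occurrences of
the winning hexamer the one closest to the cleavage site is reported.
Composition profiles exclude N from denominators and drop windows with
more than 10% N. Conservation profiles average per-base scores around
pASs, excluding coding-sequence positions and missing track positions
(missing is never treated as zero).

## Trajectories

Replicate-mean PPAU per (tissue, stage) forms one trajectory per gene
per tissue. Trajectories defined at fewer than 3 stages or with zero
variance are excluded with reason codes. The remainder are z-scored
across stages (ddof = 1) and clustered by k-means on shape
(deterministic seed, k selected by mean silhouette over k = 2…6).
Cluster membership is non-exhaustive: members farther from their
centroid than mean + 1 sd of member distances are released as
unassigned, keeping cluster shapes tight at the cost of dropping the
most extreme ~10–15% of members.

A gene is called **PPAU-decreasing** when (i) its cluster centroid
trends downward, (ii) its own Spearman ρ against stage is negative, and
(iii) its first-to-last-stage PPAU decline is ≥ 20 points. Criterion
(iii) is essential: z-normalized shapes carry no amplitude, so without
it decreasing-shaped noise in stable genes passes. With it, recovery on
planted data reaches sensitivity ≥ 0.90 at precision ≥ 0.99.

## Regulatory context

Per gene: cUTR (stop → proximal pAS, present in all isoforms), aUTR
(proximal → distal, only in longer isoforms), and a disjoint partition
into proximal/middle/distal regions (middle ends at the last middle
pAS; 2-pAS genes have no middle region; SPA genes only a cUTR).

- **Motif enrichment**: PWM log-odds scanning (pseudocount 1e-3,
  threshold 0.8 × maximum attainable score, windows with non-ACGT bases
  never hit); per motif, a 2×2 table of genes with ≥ 1 hit in aUTR vs
  cUTR feeds a one-sided Fisher exact test, Bonferroni-corrected over
  the motif count, significant at 1e-3.
- **CLIP peaks** count a gene at ≥ 1 bp overlap; usage-by-peak-status
  contrasts report rank-sum p per condition plus a
  difference-of-differences interaction summary.
- **miRNA sites** are short, so a site belongs to the segment containing
  its midpoint; only high-confidence sites (score ≥ 50) count; density
  is sites/kb.
- **TEs** are long, so coverage is base-pair fraction after merging
  overlapping copies per family (no double counting).

## Statistical kernels

Implemented in `apadyn._stats` and verified against independent oracles
(exact integer/rational enumeration, textbook formulas, per-base brute
force):

- Fisher exact on 2×2 tables via the hypergeometric pmf computed from
  vectorized log-binomial coefficients (`gammaln`), two-sided with a
  1e-9 relative tie tolerance. The log-space formulation keeps a full
  enumeration of all ~316k tables with n ≤ 50 under ten seconds.
- Pearson chi-squared (1 df, no continuity correction by default; zero
  margins yield p = 1).
- Wilcoxon rank-sum: exact enumeration for tie-free samples with both
  n ≤ 20, tie-corrected normal approximation otherwise.
- Pearson over pairwise-complete entries; Spearman with mid-ranked
  ties.

## Synthetic data generator

`GeneratorConfig` + seed fully determine the dataset (byte-identical
files on re-runs; seed is mandatory). Genes are laid out in
non-overlapping slots on two chromosomes, both strands ~50:50. Defaults
(all configurable):

| Parameter | Default | Rationale |
|---|---|---|
| `pas_count_probs` | .536/.232/.122/.07/.04 | ≈46% of genes get > 1 pAS |
| `signal_probs` (AATAAA) | .512/.289/.309/.435 (SPA/prox/mid/distal) | class-conditional planted frequencies the pipeline must recover |
| `plus_one_a_probs` | .85/.85/.83/.78 | adenine at +1 |
| `delta_ppau_total` | 30 | planted linear PPAU change across stages |
| `ppau_tissue_sd` / `ppau_stage_sd` | 6 / 2 | tissue effect 3× stage effect |
| `ppau_noise_sd`, `replicate_noise_sd` | 3 / 3 | stage- and replicate-level noise |
| `te_coverage` | .26/.456/.512 (prox/mid/distal region) | rising TE content toward distal UTR |
| `te_segment_prob` | 0.8 | leaves TE-free segments for stratified contrasts; occupied segments compensate via a per-class length-balanced greedy rule so class-level coverage stays on target |
| `mirna_density_per_kb` | 1.5/1.0/0.6 | density falls toward distal regions; placement is thinned where the matching isoform is highly expressed, planting a negative expression-vs-sites correlation |
| `n_decoy_pwms`, `pwm_sharpness` | 20, 0.97 | one planted aUTR-enriched motif among sharp random decoys |

Planted decreasing genes carry the planted motif consensus in their
aUTR with probability 0.6 (cUTR 0.05) and attract CLIP peaks;
conservation is drawn per 10-bp bin around coding (mean 2.0), TE
(mean 0.0) and other (mean 1.0) positions, sd 0.3.

## Acceptance problem sizes

The acceptance tests choose their own problem sizes, balanced for a
single-CPU run: ~10,000 pASs for signal-frequency recovery (per-class
binomial sd ~1 pp), 1,000 genes with 200 planted decliners for
trajectory recovery, 20 seeds × 50 motifs for the enrichment null, and
2 × 10 kb brute-force instances for interval oracles. The enrichment
null uses a generator variant in which every gene has exactly two pASs,
making cUTR and aUTR geometry exchangeable — any segment-length
asymmetry would otherwise masquerade as motif enrichment.

## Limitations

- The generator plants linear PPAU trends with Gaussian noise; it does
  not model count overdispersion, mapping bias, or internal-priming
  artifacts of real 3′-seq/RNA-seq.
- Trajectory clustering assumes one dominant shape per gene per tissue
  and a shared stage grid across genes.
- Fisher p-values are exact, but Bonferroni over motifs is
  conservative when motif hits are correlated.
- Conservation is modeled as independent per-bin Gaussian noise around
  class means; real conservation tracks are autocorrelated.
- The |ΔPPAU| ≥ 20 gate is calibrated for usage measured on the 0–100
  scale with a few points of replicate noise; noisier data warrants a
  re-derived threshold.
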