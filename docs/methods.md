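# Methods

`sdmt` implements the computational pipeline of a spatial co-profiling
assay that measures DNA methylation and gene expression on the same
tissue section. Tissue pixels are addressed by pairs of combinatorial
barcodes (A × B) ligated in a microfluidic grid; the DNA library is
enzymatically converted (unmethylated C → T) before sequencing, the RNA
library carries a UMI. This note records the models, parameter choices
and numerical decisions behind each stage, and what the synthetic-data
tests do and do not demonstrate.

## The synthetic generator

The generator (`sdmt.simulate`) emulates the statistical structure the
pipeline assumes, not the sequence content of a real genome.

**Tissue.** A `grid_rows × grid_cols` pixel grid (default 50 × 50 = 2,500
pixels) is tiled by `n_regions` contiguous anatomical regions, generated
as the Voronoi cells of randomly seeded centroid pixels — the simplest
construction that guarantees contiguity.

**Genome.** Contigs of configurable length (default 600 kb + 400 kb
nuclear plus a 16-kb mitochondrial contig) are drawn with background base
frequencies (A/T 0.3, C/G 0.2); background CpG dinucleotides are 90%
depleted, mimicking vertebrate CpG depletion, and CpGs are then forced in
at `cpg_density` sites/kb (default 10), so the parameter effectively
controls the realised density. Note the toy mitochondrial fraction
(16 kb / ~1 Mb) is still ~4,000× larger than in a real mammalian genome;
per-pixel pooled metrics that mix contigs reflect this.

**Methylation truth.** CpG sites sit at `baseline_mcg` (default 0.75),
non-CpG (CH) sites at `mch_level` (default 0, the embryonic condition),
mitochondrial cytosines at 0. Each region owns `n_vmrs_per_region`
disjoint 2-kb intervals in which its CG methylation is
`clamp(baseline + vmr_delta)` (default offset −0.5); with the default
genome these cover ~2% of the nuclear sequence per region, matching the
order of magnitude a top-2% variance scan is meant to find. Methylation
state is sampled per read (no molecule lineages); PCR duplication is
emulated by re-emitting a fraction of reads verbatim, sized so the
expected duplication rate is `dup_fraction` (default 0.30, inside the
20–53% range typical of such libraries). 5-hydroxymethylation is not
modelled separately: the conversion chemistry does not distinguish it.

**Reads.** Read 2 is `barcodeB(8) + linker1(15) + barcodeA(8) +
linker2(15) + [UMI(10), RNA only] + insert(50)`. Both default linkers
contain exactly 5 cytosines and are methylation-free, as are barcodes, so
in the DNA library they deaminate at the full conversion rate
(`conversion_prob`, default 0.995). Barcode substitution errors occur at
`barcode_error` per barcode (default 0.01) and sequencing errors at
`seq_error` per insert base (default 0.001). DNA reads are emitted
uniformly along the genome from the forward strand; alignment is out of
scope, so read positions travel in the provenance table. RNA molecule
counts per (pixel, gene) are negative-binomial (gamma–Poisson, variance
μ + αμ², α = `nb_dispersion` = 0.5); each region up-regulates
`marker_genes_per_region` = 10 of the 100 genes by `marker_fold` = 4.
`n_spikein` fully unmethylated spike-in reads are added to the DNA
stream.

**What the generator does not emulate:** realistic sequence composition,
fragment-length and strand models, alignment and mapping artefacts,
bisulfite-style degradation, cell-type mixtures within a pixel, spatial
diffusion between pixels. Passing recovery tests therefore demonstrate
correctness of the estimators under the assay's idealised statistical
model, not robustness to real-data artefacts.

## Demultiplexing

DNA-library matching runs in the C→T-collapsed three-letter alphabet
(both read and whitelist collapsed), because conversion makes raw C
unobservable; whitelists are validated to be collision-free after
collapse (the generator enforces collapsed pairwise Hamming distance ≥ 2).
Up to `max_hamming` = 1 mismatch per barcode is tolerated — a common
practice default. Ties at the minimal distance are left unassigned rather
than resolved arbitrarily, protecting spatial purity at the cost of
yield; N counts as a mismatch. Reads shorter than the fixed layout are
counted as `no_match` with a reason, never silently dropped, so status
counts always sum to the input count. Linker base identities are retained
on each record for conversion QC.

## Methylation calling and QC

A cytosine read as C is *retained* (methylated or unconverted), read as T
*converted*; the level of a site is retained/(retained+converted).
Context is the cytosine plus its 3′ neighbour on the same strand (CG or
CA/CC/CT = CH). Strands are kept separate in the call table; CpG-level
analyses merge the two strands of a palindromic CpG onto the forward-C
coordinate, the convention of standard extractors. Deduplication keys on
(pixel, contig, leftmost position, strand) — the DNA library has no UMI —
keeping the first-seen read. Conversion efficiency is estimated on the
methylation-free linkers: positions read as N are excluded; other
mismatches stay in the denominator. The closed-form oracle for retention
at a context with true methylation p is `p + (1−p)(1−c)`.

The knee filter sorts reads-per-pixel descending and takes, on
(log₁₀ rank, log₁₀ (count+1)), the point of maximum perpendicular
distance to the chord between the first and last point; this
distance-to-chord construction is an explicit choice where only a
"knee-plot cut-off" is specified. A curve with maximum distance below
1e−9 is degenerate: all pixels are kept with a warning.

## VMR detection and the methylome feature space

Sparse single-pixel methylomes cannot be analysed per CpG, so 2-kb
windows stepped every 1 kb (invented defaults of the right genomic order)
are scored by the across-pixel sample variance (ddof = 1) of
coverage-shrunken residuals `cov/(cov+k) · (m − m̄)` with pseudo-count
k = 1 — a documented reimplementation of the shrinkage idea, not a
verbatim reproduction of any published scan. Windows need ≥ `min_sites`
CpGs and ≥ 10 covered pixels to be eligible; exactly
`ceil(top_fraction · n_eligible)` windows are selected (default top 2%),
ties broken by genomic order, and overlapping or book-ended selected
windows are fused into VMR intervals. Fusion is idempotent; the fused
score is the member maximum.

Per-pixel VMR levels are pooled counts over the interval's CpGs, missing
where coverage is zero. Imputation replaces missing entries by iterative
rank-r truncated-SVD reconstruction (residual matrices initialise at 0,
level matrices at the feature's observed mean; levels are clamped to
[0, 1]); observed entries are never altered, and iteration stops when the
largest update falls below `tol` (default 1e−4). The update norm
decreases monotonically on low-rank-structured fixtures; on unstructured
data the iteration can plateau without monotonicity, which is why
convergence is reported in the iteration log rather than assumed.

PMD scores pool CG methylation over user-supplied BED intervals per pixel
(a mitotic-history proxy). TSS profiles bin CpGs by strand-aware signed
distance to transcription starts (upstream negative).

## Integration and clustering

RNA counts are UMI-collapsed exact-match distinct (pixel, gene, UMI)
triples. Normalisation is median-ratio scaling followed by log1p — a
deliberate substitution of a regularised variance-stabilising model by a
simpler, contract-equivalent transform (depth-invariant input to PCA).
PCA is deterministic SVD with component signs fixed by making each
component's largest-magnitude loading positive. Defaults mirror the
analysis they reproduce where stated — 30 PCs for RNA, 10 for methylation
residuals — with graph k = 20 and Leiden resolution 0.8 as invented
defaults.

The weighted-nearest-neighbour fusion is a simplified, documented variant
of the published WNN idea; bit-compatibility is a non-goal. Per pixel and
modality m, the embedding is predicted from the k nearest neighbours
found in m (within) and in the other modality (cross); the bounded score
`d_cross/(d_within + d_cross)` ∈ (0, 1) measures m's own informativeness
and a softmax over the two scores gives weights that sum to exactly 1.
The score is bounded deliberately: an unbounded within/cross ratio
saturates the softmax and hands all weight to whichever modality is
smoothest — after low-rank imputation that is the methylome regardless of
its information content. Fused similarity is the weight-blended
exponential kernel of per-modality distances (bandwidth = mean k-NN
distance); the cluster graph uses shared-nearest-neighbour Jaccard
weights on the fused k-NN lists, partitioned by Leiden (RB-configuration
modularity, seeded) or Louvain. UMAP is visualisation-only, delegated to
`umap-learn`, and never an acceptance surface.

## Downstream statistics

Differential features use the two-sided Wilcoxon rank-sum test (exact for
small untied samples via the standard implementation, normal
approximation with tie correction otherwise; identical constant groups
are reported as p = 1). The alternative description of the stage
comparison as a signed-rank test is not implemented; the rank-sum variant
matches the reported comparisons and the unpaired design. Log₂ fold
changes use pseudo-counts 0.01 for methylation levels and 1 for
normalised expression. Both Benjamini–Hochberg (default) and Bonferroni
adjustments are offered. VMR–gene pairs are interval intersections with
an optional (strand-aware upstream) flank; methylation–expression
association is Pearson's r on jointly observed pixels with BH across
pairs, negative r being the canonical repressive direction. CpG-set
enrichment uses fold enrichment FE = O/E with E = |query|·|feature|/N and
a one-sided (greater) Fisher exact test, BH across features.

## Problem sizes in the test suite

The suite exercises the whole pipeline on scaled-down instances chosen as
the smallest sizes at which each statistical property is identifiable:
200-pixel grids and ~1 Mb toy genomes for QC-band and VMR-recovery
checks (≥10⁴ observations per estimated rate, errors within 3 Monte-Carlo
SDs), 100-pixel / 200-kb instances at ~600 reads per pixel for multimodal
cluster recovery — a depth at which the methylome modality carries region
signal, qualitatively matching the deep per-pixel coverage of the real
assay. On toy genomes with only a few hundred windows the cluster-recovery
analysis widens the VMR selection to the top 10% so that enough planted
intervals enter the feature space; the top-2% default is the
production setting.

## Known limitations

- Reads are single-end, fixed-length, forward-strand; no alignment,
  quality trimming or M-bias handling (out of scope by design).
- The WNN variant and the shrinkage constant are package-specific
  choices; numerical identity with any external implementation is not a
  goal and cluster labels may differ between library versions of the
  Leiden backend.
- `import_bismark_coverage` cannot recover strand or context from the
  coverage dialect and fills the caller-provided defaults.
- Louvain clustering uses the global NumPy RNG for seeding (an igraph
  constraint); Leiden seeding is explicit and preferred.
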