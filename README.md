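# sdmt — spatial co-profiling of DNA methylation and transcriptome

`sdmt` is a toolkit for the computational side of spatially barcoded
joint methylome + transcriptome assays: tissue pixels addressed by
combinatorial barcode pairs (A × B) on a microfluidic grid, an
enzymatically converted (unmethylated C → T) DNA library and a
UMI-carrying RNA library sequenced from the same section. It takes FASTQ
reads to per-pixel methylation calls and gene counts, QC metrics,
variably methylated regions (VMRs), multimodal clusters and downstream
statistics — and ships a synthetic-data generator with full ground truth
so every stage is testable without any download.

It is written for computational biologists building or evaluating
spatial methylome pipelines: each stage is a plain Python function over
pandas/NumPy containers, with a thin `sdmt` command-line interface for
the common steps.

## The model in brief

- **Deamination-collapsed demultiplexing.** Conversion makes C
  unobservable in the DNA library, so barcodes are matched in the
  three-letter alphabet ({A,G,T}, C↦T applied to read and whitelist);
  whitelists must stay collision-free after collapse. A full 50 × 50
  whitelist pair addresses n = 2,500 pixels.
- **Methylation calling.** A cytosine read as C is *retained*
  (methylated or unconverted), as T *converted*; the level of a site is
  retained/(retained+converted) ∈ [0, 1]. Retention at a context with
  true methylation p and conversion probability c has expectation
  p + (1−p)(1−c); conversion efficiency is estimated on methylation-free
  linker bases inside every DNA read. Low-signal pixels are removed at
  the knee of the log-log reads-per-pixel rank curve.
- **VMRs.** 2-kb sliding windows are scored by the across-pixel variance
  of coverage-shrunken residuals cov/(cov+k)·(m−m̄); the top 2% of
  eligible windows are fused into VMR intervals, giving a pixels × VMRs
  methylation/residual matrix whose missing entries are completed by
  iterative truncated-SVD (PCA) imputation.
- **Integration.** Log-normalised RNA and imputed VMR residuals are
  embedded by PCA; a weighted-nearest-neighbour fusion assigns each
  pixel modality weights (summing to 1) from within- vs cross-modality
  k-NN prediction errors, and Leiden clustering runs on the fused SNN
  graph.
- **Statistics.** Two-sided Wilcoxon rank-sum marker tests (BH or
  Bonferroni adjusted), VMR–gene pairing by interval overlap with
  Pearson methylation–expression correlation, and CpG-set fold
  enrichment FE = O/E, E = |query|·|feature|/N, with one-sided Fisher
  exact tests.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import sdmt

# a 200-pixel embryo-like dataset: 4 tissue regions, mCG 0.75, mCH 0,
# per-cytosine conversion probability 0.995
cfg = sdmt.SimConfig(grid_rows=20, grid_cols=10, reads_per_pixel_dna=100, seed=42)
ds = sdmt.simulate_dataset(cfg)

records, summary = sdmt.demux_reads(ds.dna_reads, ds.layout_dna,
                                    ds.wl_a, ds.wl_b, mode="dna")
print(summary)

calls = sdmt.calls_from_reads(records, ds.provenance, ds.truth.genome)
agg = sdmt.aggregate_calls(calls)
ret = sdmt.retention_metrics(agg.table, mito_contigs=["chrM"])
eff = sdmt.linker_conversion_from_records(records, ds.layout_dna)
print(f"duplication rate {100 * agg.duplication_rate:.1f}%")
print(f"mean mCG {ret['mCG'].mean():.2f}%  mean mCA {ret['mCA'].mean():.2f}%")
print(f"linker conversion efficiency {eff:.2f}%")
```

prints

```
{'total': 29571, 'assigned': 29545, 'no_match': 0, 'ambiguous': 26}
duplication rate 30.0%
mean mCG 72.50%  mean mCA 0.52%
linker conversion efficiency 99.51%
```

Nearly every read is assigned to its pixel (ties from barcode errors are
left unassigned rather than guessed); the duplication rate matches the
generator's 30% target; CpG retention sits in the 70–80% band expected
for ~75% true methylation at 0.995 conversion (the small deficit comes
from the region-specific hypomethylated VMR intervals and the
unmethylated mitochondrial contig); apparent mCA is the conversion
failure rate, well below 1%; and the methylation-free linkers confirm
>99% conversion.

From here, `sdmt.scan_vmrs(agg.table)` detects VMRs,
`sdmt.vmr_matrix` / `sdmt.impute_iterative_pca` build the methylome
feature matrix, `sdmt.count_rna` + `sdmt.normalize_rna` +
`sdmt.embed_pca` the RNA side, and `sdmt.wnn_fuse` +
`sdmt.cluster_graph` the integrated clusters.

The same steps are available from the shell:

```bash
sdmt simulate --out simdata/
sdmt demux --fastq simdata/dna_R2.fastq --wl simdata/whitelist.tsv \
     --mode dna --out tagged.fastq --summary summary.tsv
sdmt vmr --methcall calls.tsv --out vmrs.bed
```

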