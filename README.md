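# glycoseq

Single-cell glycan profiling by DNA-barcoded lectin sequencing, and its
integration with single-cell RNA expression.

Cell-surface glycans are read out by incubating cells with a panel of
glycan-binding proteins (39 lectins plus 2 IgG negative controls), each
carrying a releasable DNA barcode. Sequencing the released barcodes gives a
cells × probes count matrix; per-cell read depth is removed by expressing
each probe as a percentage of the cell's total barcode count. Because the
same cells can also be RNA-sequenced, the glycome and transcriptome can be
linked cell by cell — for example during the differentiation of pluripotent
stem cells into neural progenitors, where the α1-2-fucose-binding
pluripotency marker lectin rBC2LCN fades while mannose-binding probes rise.

`glycoseq` implements the computational side of this assay:

- **Barcode decoding** — each 26 bp read is trimmed of its first 3 bases and
  sliced into constant flanks and an 8 nt probe barcode; a read is assigned
  to the probe minimizing middle-barcode mismatches, tolerating at most 1
  middle and 2 flank mismatches, with ambiguous reads discarded. Panels are
  validated to pairwise middle-barcode Hamming distance ≥ 3, which makes
  one-mismatch decoding unambiguous.
- **QC and normalization** — Otsu's method (maximize between-class variance
  w₀w₁(μ₀−μ₁)² over candidate thresholds) removes low-total cells; percent
  normalization (100·xᵢ/Σx), centered log-ratio
  (ln(x+1) − mean ln(x+1) per probe), and RNA log-normalization
  (ln(1 + 10⁴·x/colsum)) prepare the matrices.
- **Statistics** — the Brunner–Munzel rank test of stochastic equality
  (midrank effect estimate p̂ = P(X<Y) + ½P(X=Y), t reference with
  Satterthwaite degrees of freedom), Bonferroni and Benjamini–Hochberg
  corrections, probe–probe Pearson correlation, mean-centered PCA, and the
  adjusted Rand index.
- **PLS integration** — NIPALS partial least squares on paired matrices,
  X = TP′ + E and Y = UQ′ + F with components maximizing cov(T, U); the
  gene–lectin association matrix is A = PQ′, and per-component weights rank
  genes for downstream enrichment.
- **Pseudotime dynamics** — given an externally inferred pseudotime, each
  feature is fitted with a cubic-spline Gaussian model and tested against a
  flat model by an exact F-test, with BH correction (q < 0.05) and LOESS
  curves for display.
- **Simulation** — read-level (PCR-efficiency bias, substitution errors) and
  matrix-level (two populations, planted gene–lectin association blocks,
  planted pseudotime trends) generators with recorded ground truth, so every
  stage is testable without external data.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/01_simulate_and_count.py` simulates an equimolar barcode
mix (4 cells × 5,000 reads, 1% substitution errors) and decodes it:

```
      category  reads
         total  20000
      assigned  19946
    unassigned     54
exceeds_middle     49
 exceeds_flank      5
     ambiguous      0
     malformed      0

cells x probes: (4, 41)
mean |decoded - true| per entry: 0.34 counts (true entries average 122)
```

99.7% of reads carry a decodable barcode despite the injected errors, and
the decoded counts sit within a fraction of a count of the simulated truth.
`examples/04_pls_association.py` fits PLS on simulated paired RNA/glycan
matrices and recovers the planted 10-gene × 3-lectin association block with
precision 1.00 at k = 30; `examples/05_pseudotime_dynamics.py` flags exactly
the three planted dynamic lectins at q < 0.05, with the pluripotency-like
marker called "decreasing".

The same stages are available as a command line:

```sh
glycoseq simulate reads --seed 7 --out sim/
glycoseq count --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --panel sim/panel.tsv --index-map sim/index_map.tsv --out counts.tsv
glycoseq qc --counts counts.tsv --out kept.tsv
glycoseq normalize --counts kept.tsv --mode percent --out percent.tsv
```

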