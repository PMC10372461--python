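# peakbench

Benchmarking toolkit for comparing ChIP-style peak calls against a reference
peak set, built around five pieces:

- **`peakbench.genome`** — BED / chrom.sizes I/O and interval algebra on
  0-based half-open coordinates: sorting, merging peaks separated by at most a
  gap (default 150 bp), genomic complement, and fractional-overlap
  intersection (default: ≥20% of the query interval's length, accumulated
  across the reference union).
- **`peakbench.concordance`** — interval-level confusion matrix (TP/FP on the
  query side, TN via complements), sensitivity / specificity / PPV, and the
  optimal condition found as the crossing of the sensitivity and specificity
  curves under piecewise-linear interpolation in log10(cell number), with a
  tolerance plateau.
- **`peakbench.metagene`** — scaled metagene profiles (upstream flank, scaled
  gene body, downstream flank) reporting ln(observed/expected) signal,
  unpaired two-sided rank-sum comparisons of profiles and RPKM vectors, and
  pairwise Pearson correlation of binned read counts.
- **`peakbench.libstats`** — library accounting: percent unique
  non-duplicated reads (denominator = 2 × read pairs), percent of reads to
  keep when downsampling to a uniquely-aligned target (default 3.8 M, capped
  at 100%), fragment-range extension midpoint, and qPCR amplification-cycle
  calling (one third of plateau fluorescence; a slope-based variant is
  available).
- **`peakbench.simulate`** — synthetic genomes, gene annotations, reference
  peak sets, degraded query peak sets (planted recall, boundary jitter, peak
  splitting, background false peaks), and Poisson binned counts — all pure
  functions of a config + seed, so every pipeline stage is testable with
  known ground truth and byte-identical reruns.

## CLI

A single `peakbench` entry point with one subcommand per stage. Every run
writes a `manifest.json` with the resolved parameters into the output
directory; failures exit non-zero with a one-line message and remove partial
outputs.

```sh
# merge fragmented peaks (gaps <= 150 bp)
peakbench merge --input peaks.bed --genome genome.sizes --gap 150 --out-dir out/

# confusion counts + metrics for a query condition vs a reference
peakbench concordance --query q.bed --reference r.bed --genome genome.sizes \
    --gap 150 --min-fraction 0.2 --out-dir out/

# sensitivity/specificity crossing from a per-cell-number metrics table
peakbench optimum --series metrics.tsv --out-dir out/

# metagene enrichment profile over plus-strand genes
peakbench metagene --peaks peaks.bed --genes genes.bed --genome genome.sizes \
    --strand + --out-dir out/

# library accounting table + qPCR cycle calling
peakbench qc --table libraries.tsv --qpcr curve.tsv --out-dir out/

# synthetic dataset with known ground truth (seed required)
peakbench simulate --config sim.yaml --seed 7 --out-dir sim/
```

`--config` accepts a flat YAML file mirroring the flag names; explicit flags
win over config values.

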