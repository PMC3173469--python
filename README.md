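# ncycle

A desk-scale toolkit for functional-gene amplicon surveys of soil
nitrogen-cycling communities (nifH, archaeal/bacterial amoA, nosZ, 16S).
It covers the full analysis workflow:

- **`ncycle.synthetic_community`** — generators for every pipeline input
  with known ground truth: reference protein sets, barcoded reads with
  planted chimeras (two-parent crossovers) and frameshifts (1-bp indels),
  planted monotonic abundance trends, qPCR dilution series, T-RFLP peak
  tables. Deterministic given a seed.
- **`ncycle.demux_qc`** — raw-quality screen (length ≥ 50, no `N`, mean
  Phred ≥ 20), exact-barcode demultiplexing, degenerate-primer matching
  with re-orientation of reverse reads, post-trim length filter (≥ 350 bp),
  and a per-stage filter ledger with percentage accounting.
- **`ncycle.translated_filter`** — six-frame Smith–Waterman search
  (BLOSUM62, Karlin–Altschul E-values) against a reference protein set,
  and frame-consistency verdicts: disjoint regions of a read hitting the
  same reference in different frames ⇒ frameshift; disjoint regions
  hitting different references ⇒ chimera. Valid reads are translated in
  their best hit's frame.
- **`ncycle.otu_cluster`** — dereplication (exact + prefix duplicates,
  longest representative), pairwise alignment distances (terminal gaps
  excluded, gap run = one difference), furthest-neighbor OTU clustering,
  analytic rarefaction, and hypergeometric re-sampling to a common depth.
- **`ncycle.trend_analysis`** — monotonic trend calls per (taxon, crop)
  across three timepoints (increase/decrease strict; appear/disappear
  keyed on detection) and per-gene changed-phylotype summaries.
- **`ncycle.qpcr_quant`** — standard-curve fitting (`E = 10^(-1/slope)`),
  sample-derived standard copy numbers (660 g/mol per ds bp), copies per
  gram of dry soil with extraction-efficiency correction, one-way ANOVA +
  Tukey letters, and rate-vs-log-abundance regression.
- **`ncycle.trflp_ordination`** — in-silico terminal restriction digests
  (AluI `AG^CT`, HhaI `GCG^C`), peak filtering (50 bp ≤ size ≤ product
  length, area > 500) and normalization, Bray–Curtis distances, rank-based
  ANOSIM with permutation p-values, and correspondence analysis.

## Command-line interface

The `ncycle` command exposes one subcommand per stage:

```sh
# generate a synthetic survey (reads, references, barcodes, ground truth)
ncycle simulate --seed 1 --out-dir sim

# quality screen + demultiplex + primer screen, per-sample FASTA out
ncycle demux --reads sim/reads.fastq --barcodes sim/barcodes.tsv \
    --fwd-primer TGCGAYCCSAARGCBGACTC --rev-primer ATSGCCATCATYTCRCCGGA \
    --out-dir demuxed

# translated frameshift/chimera screening
ncycle screen demuxed/*.fasta --refs sim/refs_aa.fasta --out-dir screened

# amino-acid OTU clustering at 90% similarity + rarefaction
ncycle cluster screened/*.valid.faa --cutoff 0.10 --out-dir clustered

# monotonic trend calls
ncycle trends --table otu_table.tsv --sample-map map.tsv --out calls.tsv

# qPCR standard curve + absolute quantification
ncycle qpcr --dilutions dil.tsv --plate plate.tsv --dna-per-g 6230 \
    --extraction-eff 0.30

# T-RFLP filtering, Bray-Curtis, ANOSIM, correspondence analysis
ncycle trflp --peaks peaks.tsv --amplicon-len 453 --groups groups.tsv \
    --permutations 999 --seed 1
```

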