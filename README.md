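# m6akit

Downstream m⁶A epitranscriptome analysis as a tested, reusable pipeline:
from binned IP/Input coverage to m⁶A signal tracks, peak annotation and
enrichment, gene-level m⁶A calls, maternal-decay/ZGA gene classification,
miRNA-targeting and translation-efficiency association, and locus-level
retrotransposon m⁶A quantification — plus a synthetic-data generator that
emulates the shape of the real inputs so every stage is verifiable at desk
scale with planted ground truth.

## Modules

| module | what it does |
| --- | --- |
| `m6akit.io` / `m6akit.config` / `m6akit.cli` | GTF / BED / narrowPeak / bedGraph / FASTA / TSV readers and writers (0-based half-open internally), YAML run configuration, pipeline CLI |
| `m6akit.simulate` | synthetic genome, gene models, expression classes, IP/Input tracks with planted stop-codon peaks, repeat loci, miRNA and Ribo/mRNA tables, Ctrl-vs-inhibitor pairs |
| `m6akit.signal` | binned RPKM tracks, per-bin m⁶A signal `log2((RPKM_IP+1)/(RPKM_Input+1))`, Pearson/PCA/clustering sample similarity, naive run-length peak caller |
| `m6akit.annotate` | feature hierarchy stop_codon > 3'UTR > 5'UTR > CDS > exon > intron > intergenic, log2 observed/expected enrichment, metagene coordinates on [0,3), gene-level m⁶A union calls, RRACH counting |
| `m6akit.dynamics` | median-of-ratios normalization, M-decay / Z-decay / ZGA / constant classification, entropy specificity, human–mouse homolog expression categories, Wilcoxon / Fisher comparisons with five-number summaries |
| `m6akit.translation` | miRNA RPM normalization, conserved-target weighting (Σ log10 RPM), translation efficiency `(Ribo+1)/(mRNA+1)` with FPKM ≥ 10 filter, per-region TE grouping |
| `m6akit.retro` | repeat completeness (≥ 0.9) and full-length-ERV architecture filters, exon-overlap exclusion, max-over-bins locus scoring, subfamily summaries, element-scaled profiles, Ctrl-vs-treated comparison |

## CLI

Every subcommand reads one YAML config (thresholds are `RunConfig` keys; an
`outdir` working directory; a `simulate:` mapping with generator overrides):

```yaml
outdir: run1
bin_size: 10
similarity_window: 1000
simulate:
  n_genes: 60
  seed: 7
```

```sh
m6akit simulate --config run.yaml   # synthetic dataset + ground truth
m6akit signal   --config run.yaml   # m6A signal tracks + sample similarity
m6akit annotate --config run.yaml   # peak features, enrichment, metagene
m6akit genes    --config run.yaml   # gene-level m6A calls per stage
m6akit classify --config run.yaml   # M-decay / Z-decay / ZGA / constant
m6akit compare  --config run.yaml   # human-mouse homolog categories
m6akit mirna    --config run.yaml   # miRNA targeting association
m6akit te       --config run.yaml   # translation-efficiency association
m6akit retro    --config run.yaml   # retrotransposon filtering + scoring
m6akit report   --config run.yaml   # aggregate report.json
```

Outputs are TSV (tab-delimited, header row, `.` for missing) plus a
`pipeline.log` that echoes the configuration and records input/output
record counts for every filter.

## Conventions

* All internal coordinates are 0-based half-open; GTF converts at the I/O
  boundary; bedGraph resampling uses length-weighted means.
* Peak–transcript intersection is exon-level by default (span mode behind a
  flag); the stop-codon feature is the annotated stop ± 200 bp in genomic
  space.
* Tracks are exchanged as bedGraph (text); bigWig is not emitted.
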