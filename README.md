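# subtelo

Simulation and analysis of subtelomeric facultative heterochromatin
(H3K27me2/3) dynamics under chromosomal rearrangement, as a tested,
reusable desk-scale pipeline. The package simulates genomes whose linear
ends carry (TTAGGG)_n telomere arrays and whose methylation domains are
either *position-dependent* (maintained only near telomere repeats) or
*position-independent*, applies rearrangements (insertional / reciprocal /
quasiterminal translocations, deletions, telomere-repeat insertions,
chromosome circularization, segmental duplication) with exact coordinate
liftover, and then runs the analysis stages against the simulated truth:

- `subtelo.genome_model` — genome/rearrangement data model, liftover,
  telomere distance, ground-truth methylation re-evaluation
- `subtelo.synthetic_data` — wild-type genome generator, strain scenarios,
  ChIP/input and paired-read simulation, SNPome and RNA-count generators
- `subtelo.coverage_norm` — 100 bp / 50 bp sliding-window coverage,
  mapped-read-ratio scaling normalization, 350/500 bp display smoothing
- `subtelo.domain_analysis` — threshold/merge/min-size domain caller,
  gained / lost / invariant differential classification through a liftover,
  subtelomeric extension and anchored-span statistics
- `subtelo.snp_parse` — 70-nt trim/filter, exact-match allele-specific read
  assignment against a SNPome, smallest-file allele scaling, per-parent
  profiles
- `subtelo.breakpoints` — discordant-pair / split-read evidence, single-
  linkage clustering with a minimum call weight, outward-primer fusion test
- `subtelo.telomere_repeats` — exact (TTAGGG)_n array finder and
  terminal/interstitial classification
- `subtelo.expression_stats` — library-size normalization, log2(strain/WT)
  by domain class, qPCR-style mean/SD/95% CI summaries, two-sample t tests
- `subtelo.pipeline` / `subtelo.cli` — seeded end-to-end runs with JSON
  manifests and a subcommand CLI

All generators are pure functions of (params, seed); identical inputs give
byte-identical outputs.

## CLI

```sh
subtelo simulate --seed 1 --outdir out --with-sequence --scenario tert
subtelo coverage --alignments reads.bed --genome-json out/wt/genome.json --out chip.bedgraph
subtelo call-domains --chip chip.bedgraph --input input.bedgraph \
    --genome-json out/wt/genome.json --out calls.bed
subtelo diff-domains --ref wt_calls.bed --alt strain_calls.bed \
    --liftover out/tert/liftover.tsv --out differential.bed
subtelo snp-parse --reads reads.fastq --fasta wt/genome.fa \
    --genome-json wt/genome.json --snpome snpome.tsv --outdir parsed/
subtelo breakpoints --sam pairs.sam --out calls.bedpe
subtelo telomeres --fasta genome.fa --out arrays.bed
subtelo expression --table expr.tsv --strain s --wt wt \
    --classes differential.bed --genes genes.gff3 --out summary.json
subtelo run-all --config config.json --seed 1 --outdir run/
```

Formats: genomes as FASTA + JSON sidecar (lengths, circularity, telomere
arrays, truth domains), genes as GFF3/BED6, domains and calls as BED6
(class/label in the name column), coverage as bedGraph, alignments as BED6
or a minimal SAM dialect, SNPomes as TSV (or paired FASTA), reads as FASTQ.
Coordinates are 0-based half-open except GFF3 (1-based inclusive).

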