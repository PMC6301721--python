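# dnvburden

Analysis toolkit for de novo coding variants in trio cohorts:

- **Trinucleotide-context mutation model** (`dnvburden.mutation_model`) —
  per-gene baseline rates by functional class (synonymous / missense /
  D-mis / nonsense / splice / frameshift) from a 192-entry context rate
  table, enumerated over the longest transcript; expected counts under a
  cohort (2N autosomal alleles, 2·F + M on chrX non-PAR).
- **Burden statistics** (`dnvburden.burden_stats`) — one-sided Poisson
  burden tests with exact (Garwood) fold-enrichment confidence intervals,
  stratified by phenotype group and gene set (including a pLI ≥ 0.5
  "constrained" partition), plus a per-gene recurrence test with
  genome-wide Bonferroni correction (0.01 / 20000 by default).
- **Placement simulation** (`dnvburden.placement_sim`) — re-places observed
  variants across the exome conserving count, trinucleotide context,
  alternate base and deleteriousness category per simulation; empirical
  gene-set enrichment with the add-one p estimator.
- **Convergence analyses** (`dnvburden.convergence`) — expression rank
  percentiles (with max-expression ortholog resolution), burden per
  expression quartile, a target-gene expression z-score shift test
  (two-sample Kolmogorov–Smirnov), and a hypergeometric enrichment map
  (BH-FDR, 25–750 size band, similarity = mean of Jaccard and overlap
  coefficients) emitted as GraphML + TSV.
- **Variant I/O and filters** (`dnvburden.cohort_io`) — de novo variant
  tables (TSV), GMT gene sets, pLI tables, BED coverage masks; functional
  classification (D-mis = missense with CADD ≥ 25; LGD = frameshift,
  nonsense, canonical splice, stop-loss) and the stringent candidate
  de novo read-evidence filters; Ts/Tv summary.
- **Synthetic data** (`dnvburden.synthetic_data`) — toy exomes, symmetric
  rate tables, null and risk-spiked trio cohorts, expression matrices and
  gene sets, all pure functions of (config, seed) with truth manifests.

## CLI

All commands accept a global `--seed` and `--log-level`:

```sh
# emit a synthetic input bundle with ground truth
dnvburden --seed 1 simulate --out-dir demo --n-genes 60 --n-trios 300

# burden table (Table-2-style TSV) with a constrained-gene partition
dnvburden burden demo/denovo.tsv --pack demo/transcripts.tsv \
    --fasta demo/genome.fa --rate-table demo/rates.tsv \
    --pli demo/pli.tsv --out burden.tsv

# recurrence scan with per-gene Poisson tests
dnvburden gene-test demo/denovo.tsv --pack demo/transcripts.tsv \
    --fasta demo/genome.fa --rate-table demo/rates.tsv --out genes.json

# context-preserving placement simulation against GMT gene sets
dnvburden --seed 7 placement-sim demo/denovo.tsv --pack demo/transcripts.tsv \
    --fasta demo/genome.fa --gene-sets demo/gene_sets.gmt \
    --n-sims 50000 --out placement.tsv
```

Other subcommands: `classify`, `filter`, `expr-burden`, `target-shift`,
`enrich-map` (see `dnvburden <cmd> --help`).

## File formats

- De novo table: TSV with columns `chrom, pos, ref, alt, proband, sex,
  group, gene, consequence, cadd_phred, platform` (+ optional `context`);
  1-based positions.
- Rate table: whitespace-delimited `from-trinucleotide to-trinucleotide
  rate`, header tolerated; strand-complement lookup supported.
- Transcript pack: TSV `gene, transcript, chrom, strand, cds_intervals
  (1-based inclusive, `start-end;start-end`), chrx_nonpar` — a fully
  offline alternative to GTF + FASTA (GFF3 loading via gffutils is also
  provided).
- Gene sets: GMT or one-gene-per-line; pLI: 2-column TSV; coverage mask:
  BED (0-based half-open).
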