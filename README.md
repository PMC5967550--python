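# urnafate

Locus-level functional-evidence analysis for multicopy small-RNA gene
families (the uridine-rich snRNAs U1, U2, U4, U5, U6 and the snoRNA U3).

These families are ancient and essential, yet mammalian genomes carry
dozens to hundreds of copies of each — most of them plausibly the product
of LINE/L1-mediated retrotransposition rather than of selection.  A
retrotransposed copy that lands without a promoter is *dead on arrival*
(DOA): it is expected to decay and should show no evidence of function.
`urnafate` implements the informatic tests that separate candidate
functional copies from DOA retrogenes, each behind its own module:

- **synteny** — cross-species synteny groups of same-family loci from an
  alignment-block map, with the greedy seed-and-remove rule (one-hop by
  default, connected components optionally).
- **dollo** — Dollo-parsimony reconstruction of each group's origin node
  and losses on a rooted species tree (single gain at the MRCA of the
  presence leaves, minimal loss set), yielding a conservation-depth label
  per locus.
- **retro_signatures** — retrotransposition hallmarks: the adenosine
  fraction of the 30 bp transcript-orientation downstream flank (flagged
  when >50%), and LINE/L1 repeat annotations overlapping 100 bp flanks.
- **expression** — pol-II ChIP peaks within 500 bp (inclusive) of the TSS
  per cell line (categories: no site / ≥1 cell line / all cell lines);
  unique-read counting (reads with >1 mapping location or overlapping ≥2
  loci are discarded) with RPKM
  `[reads/(mapped/10^6)]/kb`; CAGE peak-to-locus assignment by
  strand-matched 5′ ends within 500 bp with protein-coding-TSS exclusion
  and ambiguity/sparsity filters; TMM normalization to tags-per-million.
- **divergence** — mean ± SD of pairwise nucleotide differences within a
  family alignment; per-locus counts of segregating variants
  (folded MAF `min(AF, 1−AF) > 0` in ≥1 population).
- **evidence** — per-locus integration, the promoter-category summary
  table with its percent-formatting rule, the four-way support partition
  (promoter+expression / promoter only / expression only / none), and a
  two-sample Kolmogorov–Smirnov comparison of covariance-model (CM) bit
  scores between loci with and without promoter evidence (asymptotic or
  exact-permutation p-values).
- **synthetic_data** — a continuous-time birth–death simulator of copy
  turnover along a species tree that emits *every* input the pipeline
  consumes (GFF3, FASTA, alignment-block TSV, Newick, BED peaks, read
  tables, CAGE tables, Infernal-style tblout, VCF) plus ground-truth
  labels, so the whole pipeline is testable without any downloads.
- **io_formats / cli** — strict parsers normalizing everything to 0-based
  half-open coordinates, and the `urna-fate` subcommand front-end.

## Worked example

Simulate a dataset and run every stage end to end:

```bash
urna-fate run-all --seed 42 --out demo/
```

`demo/` then contains the emitted inputs (`inputs/`), the synteny groups,
the presence/absence matrix, Dollo reconstructions, per-species evidence
tables and summaries.  With seed 42 the human support partition
(`demo/support_human.tsv`) reads:

```
family  promoter+expression  promoter_only  expression_only     none  n_loci
    U1             0.400000            0.0              0.0 0.600000       5
    U2             0.750000            0.0              0.0 0.250000       4
    U3             1.000000            0.0              0.0 0.000000       3
    U4             0.666667            0.0              0.0 0.333333       3
    U5             0.800000            0.0              0.0 0.200000       5
    U6             1.000000            0.0              0.0 0.000000       3
```

Each row partitions one family's loci over the four evidence bins; with
the default noise-free settings the `promoter+expression` fraction is
exactly the simulator's functional fraction and `none` is exactly its DOA
fraction.  The first Dollo reconstructions (`demo/dollo.tsv`):

```
group_id origin_node  n_losses
   U1.g0     amniote         0
   U1.g1     amniote         0
   U1.g2     primate         0
   U1.g3       human         0
```

The two `amniote`-origin groups are the ancestral functional copies; the
`primate`/`human` groups are younger retrocopies, the typical age profile
of these families.  Individual stages are available as subcommands
(`urna-fate simulate|synteny|dollo|polya|repeat-flank|polii|quant|cage|
pairwise-diff|snp-load|integrate|report`) over the same file formats.

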