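# Methods

## The model

`urnafate` treats each small-RNA gene family as a population of copy
lineages evolving on a rooted species tree under a continuous-time
birth–death process. A *functional* copy (one that landed with a working
pol-II promoter) spawns new genomic copies as a Poisson process with rate
`birth_rate` per unit branch length; each new copy captures a promoter
with probability `promoter_capture_prob` and is otherwise dead on arrival
(DOA). Functional copies persist indefinitely and spawn recursively
within a branch; a DOA copy decays and ceases to be annotatable after an
exponential lifetime with rate `death_rate`. Every copy lineage is born
exactly once, on one branch — which is precisely the single-gain
assumption under which Dollo parsimony reconstructs gene content, and the
reason Dollo is the matching reconstruction method for retrogene
turnover: origins are unique, losses are free.

Sequence evolution is deliberately minimal. Copies are fixed-length
(`locus_len`, default 150 bp, no indels) and substitute JC-style at
`subst_rate` per site per unit time; functional copies are under
purifying selection, modeled as a multiplier `functional_constraint`
(default 0.1) on the neutral rate. This single knob is what makes
covariance-model (CM) bit scores informative in the simulation: emitted
scores are `cm_base_score − cm_penalty_per_sub × d` where `d` is the
Hamming distance to the family's ancestral sequence, so DOA copies drift
to low scores while functional copies stay near the maximum — the same
qualitative contrast the KS comparison of CM scores by promoter status is
designed to detect. New copies carry a 3′ poly-A remnant of
`polya_init_len` (default 30) adenosines directly downstream in
transcript orientation; each tail base substitutes away from A at
`polya_decay_rate`, making the 30 bp downstream A-fraction a measurable
truth. The ancestral (root) copies are not retrocopies and carry no tail;
by default there are `n_root_loci = 2` of them per family, matching the
observation that deep conservation in these families is limited to one
or two copies.

## Defaults and what they portray

| parameter | default | meaning |
|---|---|---|
| `birth_rate` | 0.4 | retrotranspositions per functional copy per unit time |
| `death_rate` | 0.5 | loss of annotatability per DOA copy per unit time |
| `promoter_capture_prob` | 0.25 | chance a new copy lands functional |
| `subst_rate` | 0.02 /site | neutral substitution rate |
| `functional_constraint` | 0.1 | purifying-selection multiplier |
| `polya_init_len` / `polya_decay_rate` | 30 bp / 0.1 | tail length and decay |
| `n_root_loci` | 2 | ancestral functional copies per family |

The bundled species tree has six leaves (human, chimp, mouse, rat,
chicken and labeled internal nodes primate/rodent/mammal/amniote) and
root-to-leaf depth 4 time units; rates are quoted against that scale. No
field estimates of these rates exist — the defaults were chosen once to
produce the qualitative regime the analysis targets (tens of copies per
family per genome, a majority of them DOA, a minority deeply conserved)
and are not fitted quantities.

## Simulator design choices

**Structure vs. sequence streams.** Structural randomness (birth times,
capture coin-flips, DOA lifetimes, strands) and sequence-level randomness
(substitutions, tail decay) come from separate generator streams derived
from the one seed. DOA lifetimes are drawn as standard exponentials
scaled by `1/death_rate`, and tail bases flip when a uniform draw falls
below `1 − exp(−rate × age)`. Consequently a sweep over `death_rate` or
`polya_decay_rate` at fixed seed is coupled by common random numbers:
presence sets shrink monotonically in the death rate and surviving tail
adenosines shrink monotonically in the decay rate, which is what the
monotonicity tests exercise.

**Per-leaf sequence materialization.** Substitutions are drawn per leaf
from the family's ancestral sequence over the lineage's exposure time
(constrained rate before the copy's birth, fate-dependent rate after),
not propagated along branches. Sister species therefore do not share
derived alleles. None of the downstream statistics the pipeline computes
(within-species pairwise differences, per-species CM scores, read
multi-mapping) depend on cross-species allele sharing, but analyses that
would — e.g. building gene trees from the emitted sequences — should not
be attempted on this generator.

**Shared coordinate frame.** Orthologous copies occupy identical
coordinates in every carrying species (one slot of 1 kb per lineage on a
per-family chromosome), and the true alignment map contains one block per
lineage spanning its slot in all carriers. This makes the noiseless map
exact by construction; `map_drop_prob` removes whole blocks to emulate
unaligned regions. Real alignment maps have coordinate noise and partial
blocks that this generator does not model, so passing the noiseless
recovery tests demonstrates correctness of the grouping logic, not
robustness to alignment error.

**Expression truth.** Functional loci receive Poisson(`mean_depth`)
reads per sample and one CAGE peak at their 5′ end with
Poisson(`cage_mean`) tags per sample; DOA loci receive nothing (plus
optional `cross_map_noise` unique-looking reads). A read from a locus
with a same-family paralog within `multimap_max_mismatches` (default 3)
is emitted multi-mapped with probability equal to its identity to the
closest such paralog — so near-identical paralogs lose unique-read signal
exactly as they do under real stringent counting, while CAGE assignment,
being positional, is immune. Promoter peaks cover the TSS of functional
loci in every simulated cell line with `promoter_detect_prob` (default
1.0); variant loads are Poisson with separate means for functional
(1.5) and DOA (5.0) copies.

## Pipeline conventions and numerical choices

- **Coordinates** are uniformly 0-based half-open internally; GFF3 and
  VCF are converted at the parser boundary, BED passes through.
- **Synteny grouping** iterates species in tree-leaf order and loci by
  (chrom, start, locus_id); expansion is one hop from the seed (the
  literal reading of the seed-and-remove loop); `--transitive` computes
  connected components instead. Overlap threshold ≥1 bp, same family
  required, strand ignored.
- **Dollo**: origin = MRCA of presence leaves; the loss set is the
  branches above maximal all-absent clades inside the origin subtree.
  This attains the single-gain minimum (verified against exhaustive
  search in the tests). Unrooted input trees are rejected, not silently
  rooted. Clade labels are configuration, not hard-coded; an unlabeled
  origin falls back to its nearest labeled ancestor.
- **Windows** ("within 500 bp") are inclusive at both the pol-II and
  CAGE uses. Pol-II distance is strand-agnostic (ChIP peaks are
  unstranded); CAGE assignment is strand-matched.
- **Poly-A**: flank read in transcript orientation (reverse-complemented
  on minus strand; switchable with `strand_aware=False`); threshold is a
  strict `> 0.5`; flanks truncated at contig ends keep the truncated
  length as denominator; N never counts as adenosine.
- **Unique-read counting** follows union-mode semantics: a read counts
  iff it has exactly one mapping location and overlaps exactly one locus;
  the library size is all unique reads genome-wide. Whether a read must
  be contained in a locus is unspecified in the field's descriptions;
  overlap was chosen.
- **CAGE sparsity filter** is a single pass (drop samples expressing <2
  loci, then loci expressed in <2 remaining samples); `iterate=True`
  repeats to a fixpoint. A crafted matrix where the two differ is frozen
  in the tests.
- **TMM**: reference sample = the library whose 75th-percentile count
  fraction is closest to the mean of those fractions; M/A computed over
  loci positive in both libraries; rank-based two-sided trimming at 30%
  (M) and 5% (A); weights are inverse asymptotic binomial variances;
  factors renormalized to geometric mean exactly 1; samples with
  identical composition get factor exactly 1. TPM =
  `count/(factor × library_size) × 10^6`.
- **Percent formatting** in the promoter summary: nearest integer at
  ≥2%, one decimal below 2%, rounding half away from zero; the
  denominator is all loci (the at-least-one column includes the
  all-cell-lines subset).
- **KS test**: D is the sup-distance of the two empirical CDFs; the
  asymptotic p uses the Kolmogorov distribution at
  `(√en + 0.12 + 0.11/√en)·D` with `en = n1·n2/(n1+n2)`; an exact
  permutation mode enumerates all label splits and is the default
  (`method="auto"`) for `n1+n2 ≤ 16`. Against exact enumeration the
  asymptotic p is accurate to ≤0.2 absolute for `n1+n2 ≤ 16`, with the
  worst cases in balanced tiny designs where the exact D lattice is
  coarse — hence the exact default there.
- **MAF folding**: a variant segregates if `min(AF, 1−AF) > 0` in ≥1
  requested population; an allele fixed at AF = 1.0 does not count.
  Gap-vs-base counts as a difference in pairwise distances (gap-vs-gap
  ignored); both choices are switchable.
- **tblout**: Infernal 1.1 column order assumed, indices configurable;
  when a locus yields several hits the maximum score is kept.

## Monotone responses and their regime

Two generator–pipeline responses are tested on fixed-seed grids. The DOA
poly-A flag rate is non-increasing in `polya_decay_rate` — exactly, by
the common-random-number coupling. The pipeline's species-specific locus
fraction is non-decreasing in `death_rate` *on average over a seed set*
(the test uses four seeds on the grid 0–1.0 at birth 0.8): rising death
rates preferentially prune old, multi-species DOA lineages, pushing the
survivor pool toward young single-species copies. This holds in the
pruning-dominated regime around the defaults; at death rates large
relative to the tree depth the DOA class empties entirely and the
fraction reverts toward the functional-only baseline, so the response is
not globally monotone — a property of the birth–death model itself, not
of the implementation.

## Problem sizes

Defaults were sized for interactive use: 6 families × 6 species ≈
100–150 loci per simulated dataset, 4 expression samples at mean depth
60, CAGE mean 50. The test suite's heavier pieces are the ~200-pair
Dollo-vs-exhaustive sweep, a 600-replicate comparison of leaf copy
numbers against the closed-form Yule mean `n₀·e^{λt}` (within 3 SE), the
exact-permutation KS battery (all C(16,8) splits at worst) and the
4-seed × 4-point death-rate grid; the whole suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

- No indels other than the poly-A tail; no rearrangements; JC
  substitution only; no rate heterogeneity across sites or branches.
- No cross-species allele sharing (per-leaf materialization, above).
- The simulator emits no repeat annotations, so the LINE/L1 flank flag
  defaults to false in simulated runs; the `repeat-flank` subcommand
  serves real RepeatMasker-derived TSVs.
- Probabilistic gain/loss models for gene content are out of scope by
  design: Dollo's assumption-free reconstruction matches the absence of
  any calibrated rate model for retrotransposing ncRNA.
- The one-hop vs. transitive grouping ambiguity is resolved by shipping
  both (one-hop default); on the noiseless simulator the two coincide
  because true blocks are disjoint.
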