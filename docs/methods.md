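# Methods

## Problem setting

A single male's sperm are a panel of independent meioses.  Genotyping each
sperm at the heterozygous sites of its parent yields, per cell, a haploid
mosaic of the two parental haplotypes H0/H1 with switch points at
crossovers.  Co-segregation of alleles across cells then measures the
recombination fraction r between any two loci: r ≈ 0 for tightly linked
loci, 0.5 for loci on different chromosomes.  `spermlink` uses these
fractions to place assembly contigs into chromosome-scale linkage groups,
order and orient them, and assign genetic positions — without a cross.

The data model is the vartrix sparse matrix: markers × cells with values
1 (ref allele seen), 2 (alt), 3 (both), absent = missing.  Equivalent
input/output dialects are a bulk het-site VCF plus Matrix Market file, or
a multi-sample "cell-separated" VCF with haploid genotypes (0, 1, `./.`
for missing, `0/1` where both alleles were seen; that last code preserves
doublet evidence and is this package's declared dialect).

## Pipeline

1. **Binning** (`genotype`).  Markers are collapsed into fixed,
   left-aligned, non-overlapping windows of `r` = 4000 bp per contig
   ("bins"); at ~1 het SNP per 245 bp a window holds ~16 SNPs, so even a
   0.13× cell observes most bins at least once.  The assembly reference
   collapses the diploid to an arbitrary haplotype *per site*, so raw
   ref/alt labels of the members of one window carry no common phase.
   Member markers are therefore phased against each other across cells
   before aggregation: the most-observed marker seeds the window's gauge,
   and the rest join by majority agreement with the per-cell consensus of
   already-phased members (minimum 2 shared informative cells, up to 3
   passes).  Markers that never gain cross-cell support keep the
   provisional ref-as-A labelling, which makes the degenerate single-cell
   case reduce to a plain ref/alt majority.  A cell's bin call is the
   strict majority of its phase-aligned observed members; a tie, or any
   member showing both alleles, is CONFLICT; no observation is NA.
   (An earlier design that used the provisional ref labelling for *all*
   members was measured to destroy the signal entirely — adjacent-bin
   disagreement ≈ 0.5 on clean simulation — which is why the in-window
   phasing exists.)
2. **Bin filters**.  Bins with a non-NA cell fraction below
   `NonZeroSampleRate` = 0.05 or an informative (A/B) fraction below
   `RateOfNotNASNP` = 0.001 are dropped.  All threshold comparisons in the
   package keep the boundary (≥ keeps; removal rules use strict >).
3. **Contig phasing** (`phasing`).  Seed-and-extend along bin order: a
   candidate bin links to the nearest previously phased bin when they
   share ≥ `cs` = 2 informative cells with minority fraction ≤ `p` = 0.03;
   on failure it is tested against up to `ldseqnum` = 3 previous phased
   bins before being left unphased.  The assignment has a global gauge
   freedom (H0↔H1); all downstream recombination fractions are invariant
   under it (tested).  Per-cell contig calls are the majority H over
   phased bins, NA unless the minority fraction is ≤ `b` = 0.03.  Contigs
   whose per-cell call rate is below `NonZeroPhaseRate` = 0.1 are excluded
   from linkage.
4. **Imputation**.  Each missing call is filled from the `ldseqnum` = 3
   nearest observed bins (bin-index distance, not bp, so behaviour is
   uniform across SNP-density fluctuations; distance ties break toward the
   smaller position) by strict majority, else it stays NA.  Imputation
   reads observed calls only: it never overwrites an observation and is
   idempotent.  It runs on phase-aligned H calls, not raw alleles —
   neighbour majority is only meaningful after phasing.
5. **Cell QC** (`qccells`).  Two filters, evaluated after the first
   phasing pass.  *Conflict filter*: cells with more than
   `conflict_rate_max` = 0.1 both-allele observations are removed as
   diploid (a diploid shows both alleles wherever covered; haploids with
   allele error 0.005 pass with ≫99% probability).  This is a stand-in
   for an upstream CNV-based ploidy score, which is out of scope.
   *Breakpoint filter*: over each contig's ordered non-NA observed
   H-sequence per cell (unphased bins dropped, pairs never spanning
   contigs), the switch rate = switches / adjacent informative pairs; a
   rate above 5% (strict) removes the cell as a doublet.  The 5% rule is
   interpreted as a *rate* over adjacent informative pairs because a raw
   breakpoint count is not comparable across cells of different coverage.
   Cells are never removed for low coverage alone.  The pipeline is
   two-pass: phase → QC → filter, then a full rerun with identical
   parameters on the kept cells; removed cells are never reintroduced.
6. **Linkage map** (`linkmap`).  Contig-end haplotype calls are the strict
   majority over the first/last `end_window_bins` = 5 phased bins, using
   imputed calls.  On contigs with fewer than 10 phased bins the window
   clamps to half the phased bins so the two end windows never overlap —
   clamping to the full bin count instead gives every contig under ~40 kb
   identical end calls by construction, leaving it permanently
   unorientable (measured cost: ~20% of orientable contigs).  Pairwise r between ends
   uses the gauge-fixed estimator min(d, n−d)/n over shared informative
   cells.  Contigs join a linkage group when their best eligible
   end-to-end LD = 1 − 2r ≥ `nl` = 0.9 (eligible: n ≥ `cs` shared cells
   covering ≥ `RateOfNotNALD` = 0.01 of cells); groups are graph
   components, ordered and oriented by minimising the sum of adjacent
   facing-end r (greedy best-edge chaining, then 2-opt segment reversal;
   end pairs without evidence cost the maximum 0.5).  On every simulated
   group of ≤ 6 contigs the result matches the exhaustive optimum over
   all orders × orientations (tested).  A contig's orientation is
   *reported* only when flipping it changes the flanking discordant-cell
   totals by ≥ `cs` cells; contigs with no internal recombination in any
   cell are always `?` — with centromeric crossover suppression these are
   exactly the centromeric blocks.  Whole-group reversal is
   unidentifiable; groups are reported with the physically longer arm
   first.  Genetic positions accumulate cM = 100·r (Haldane available via
   `map_function`; adjacent r here are ≪ 0.1 so the direct mapping is
   adequate); unoriented contigs get a single shared position (zero
   span), and adjacencies without evidence abut rather than inflate the
   map.
7. **Scaffolds** (`scaffold`, `ioforms`).  Groups become scaffold
   sequences with `gap_len` = 10,000 N between consecutive contigs (the
   pseudo-chromosome convention).  Unoriented contigs appear in the
   chromosome as an N-run of their own length and are emitted again as
   separate records `<group>_unoriented_<contig>`; in AGP v2.1 they are N
   gap lines with gap_type `contig`.  Assembly statistics are base-
   weighted: placed% and oriented% over contig bases; N50 is the length
   of the shortest sequence at 50% cumulative output length.  Reported
   percentages round half-up to one decimal.

## Simulator

`synthdata` generates: a diploid parent with geometric het-site
inter-arrivals (default mean 245 bp) and a per-site random choice of which
haplotype the collapsed assembly reference shows; contigs partitioning
each chromosome with ~exponential lengths, half emitted
reverse-complemented; gametes with per-chromosome crossover count
1 + Poisson(rate − 1) (obligate chiasma, default rate 1.5 — a
literature-typical fish value, user-tunable since the source data's rate
is not published) or plain Poisson, positions uniform outside an optional
hard zero-density centromeric window; and sparse cell observations with
per-site hit rate 0.13, allele error 0.005, plus doublet (union of two
gametes; value 3 where they disagree and both are hit; default 5%) and
diploid (value 3 at every hit site; default 2%) cells.  All randomness
flows from one seed; identical seeds reproduce identical outputs.

Default problem size for tests and the acceptance script: 4 chromosomes ×
2 Mb, ~25 contigs each (mean 80 kb), 1000 cells — a deliberate desk-scale
surrogate for a 456 Mb genome.  What the simulator does **not** model:
read-level artefacts (PCR chimeras, barcode collisions, mapping bias),
copy-number variation, crossover interference beyond the obligate
chiasma, and segmental misassembly.  Passing recovery tests therefore
demonstrates the statistical machinery, not robustness to every artefact
of real libraries.

## Numerical and design choices

* LD is measured as 1 − 2r ∈ [0, 1] so that `nl` = 0.9 is a usable
  threshold (r ≤ 0.05).
* Orientation evidence reuses `cs` (2 discordant cells) rather than
  introducing a new parameter — same support semantics as phase links.
* Ties everywhere break deterministically (smaller position, smaller
  contig id); reruns with identical inputs, config and seed are
  byte-identical.
* Degenerate inputs: a contig where no bin pair meets `cs` is reported
  all-unphased; empty overlap gives an undefined (NaN) r and never an
  edge; cells with zero informative pairs get breakpoint rate 0.
* The `-r` flag is implemented as a bin *width*; the flag names and
  default values mirror the upstream linkage tool so configs can be read
  side by side, but the semantics documented here are this package's own.

## Limitations

Centromeric and other recombination-free regions are placed but not
orderable or orientable from linkage alone — they surface as flat cM
blocks of `?` contigs, and only more cells (or longer contigs) shrink
them.  Contig misassemblies are not detected or split.  Group-level
reversal is conventional, not inferred.  The cM scale is linear in r and
so compresses slightly at large adjacent distances unless the Haldane
mapping is selected.
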