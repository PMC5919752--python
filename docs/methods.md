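# Methods

## Coordinates and formats

Internal coordinates are 0-based half-open, the convention of BED and
bedGraph.  Printed coordinates in yeast tables are 1-based inclusive and are
converted only at the IO boundary (`convert_coords` /
`GenomeInterval.to_1based`), so a printed 14-mer span such as
465396–465409 has width 14 internally.  Coverage is stored densely per
base; bases covered by no bedGraph record are 0, never missing, so
difference tracks are defined everywhere.  Strand is tracked on intervals
but coverage is unstranded; strand matters only for promoter assignment and
motif reporting.

## Normalization and shape metrics

ChIP and input tracks are depth-normalized by scaling the deeper library
down to the shallower (`min(totals)/own_total`), after which all signal is
in common units and the difference track d = chip − input is formed per
base.  For a region R:

- **summit**: `max d` over R, leftmost maximizer on ties (deterministic and
  order-stable).  Regions where d never rises above zero are flagged
  degenerate and carry no width/log2fc thresholds.
- **width at half max**: count of bases in R with `d ≥ summit/2`.
- **area**: sum of positive differences.
- **symmetry ratio**: `min(L, R⁺)/max(L, R⁺)` of the positive areas
  strictly left/right of the summit; defined as 1 when both are 0.
- **pileup log2fc**: `log2((mean chip + c)/(mean input + c))` with
  pseudocount c = 1.0 signal unit by default, which bounds the statistic on
  regions with zero input.  Computed as `log2(num) − log2(den)` so the
  swap antisymmetry fc(a,b) = −fc(b,a) is exact in floating point.

The metric set beyond summit height and pileup log2fc (width, area,
symmetry) is this package's own definition of "peak shape"; every threshold
is a config key.

Per-condition metrics are the arithmetic mean over contributing replicates;
replicate support counts replicates with at least one call overlapping the
consolidated span by ≥ 1 bp.

## Consolidation

Peak calls from all callers, replicates and conditions are merged per
chromosome with a configurable `max_gap` (default 0: only overlapping or
abutting calls merge).  Merging is idempotent and order-invariant; region
ids are assigned in genomic order.  Each region records the distinct
callers supporting it and per-condition replicate support.

## The confidence screen

Flags:

- **negative**: the region overlaps a maximal run of
  `d ≤ −depth_threshold` (default 20 normalized units) of length
  ≥ `min_width` (default 20 bp), detected on each condition's
  replicate-mean difference track (averaging replicates sharpens the
  signature against per-base noise).
- **hyper-ChIPable**: the region lies mostly (> 0.5 fraction) inside a gene
  body whose FPKM percentile among all loci reaches
  `hyperchip_percentile` (default 90) in at least one of the region's own
  conditions (the max across matched conditions — conservative, since an
  artifact need only be explicable by expression in one condition).

Tiers partition the regions:

- **high**: supported by every caller; and in ≥ 1 condition simultaneously
  replicate support ≥ `min_replicates` (default 2), mean summit
  ≥ `min_summit` and mean pileup log2fc ≥ `min_log2fc` (default 0.5); and
  neither artifact flag.  `min_summit` defaults to 10 normalized units —
  about background + 3 sd of the per-base difference noise at the
  generator's default background rate — and is deliberately permissive:
  the artifact flags, not the summit floor, do the rejecting.
- **rejected**: either artifact flag, or no signal at all.
- **ambiguous**: everything else.

Raising the expression of an overlapped gene can only switch the
hyper-ChIPable flag on, never off (monotonicity), and the screen is
invariant to region input order.

Promoters are the 500 bp upstream of the TSS, strand-aware — the typical
range of yeast upstream activation sequences; the window is a config key.

## Expression

FPKM is `count × 10⁹ / (length_bp × library_size)`; library sizes are
mapped-fragment totals after removing rRNA/tRNA classes, which are
extracted at high and variable abundance and would otherwise bias the
denominator.  Per-condition FPKM is the mean of per-replicate FPKM, not the
FPKM of summed counts.  Log2 fold changes default to pseudocount 0 with an
explicit error on non-positive values — no silent flooring.  Differential
significance testing (dispersion models, q-values) is out of scope.

Pearson's correlation between per-condition peak metrics and the
downstream gene's per-condition FPKM uses `scipy.stats.pearsonr` (r plus a
two-sided t-test with n − 2 df); constant vectors and n < 3 are errors, and
the condition grouping of each test is a parameter.

## Motif discovery

The sampler is the classic one-site-per-sequence Gibbs scheme: hold one
sequence out, build the PWM from the remaining sites with Dirichlet
pseudocounts `α_b = pseudocount × background_b × 4` (pseudocount 0.5 by
default, background estimated from the input sequences unless supplied),
and re-sample the held-out site position — and strand, when enabled —
proportional to the PWM/background likelihood ratio.  After each sweep a
phase-shift move greedily realigns all sites by ±1 if that raises the
total information content; site samplers otherwise lock onto the planted
motif shifted by a base.  The best configuration (information content ×
site count) across sweeps and restarts is kept, which replaces manual
curation with a reproducible, seeded selection rule.  Identical inputs and
seed give identical output.

Logo column heights are posterior mean relative entropies: frequencies are
drawn from the Dirichlet posterior (counts + prior), relative entropy
`Σ f log2(f/p)` is computed per draw, and the 2.5%/97.5% quantiles give the
95% credible interval.  Values lie in [0, 2] bits for uniform background.

Consensus scanning expands IUPAC codes to character classes and reports
all (possibly overlapping) exact matches; minus-strand hits are matches of
the reverse-complemented consensus on the forward sequence, reported at the
forward coordinate of the match start.

## The synthetic study

The generator emulates a six-condition (three TF alleles × two media)
yeast study: one 200 kb chromosome, 40 genes of 1–2 kb with ≥ 1 kb
intergenic spacing, two RNA replicates and three ChIP replicates per
condition at nominal depth 10⁶.  All stages are pure functions of
(config, seed); reruns are bit-identical.

- **Expression**: base FPKM is log-normal(meanlog 3.0, sdlog 1.2) —
  median ≈ 20 FPKM with a realistic yeast-like spread — times a per-gene,
  per-condition log-normal effect (sdlog 0.4).  The designated
  hyper-ChIPable cohort draws from log-normal(meanlog 6.2, sdlog 0.25): a
  tight, very highly expressed block emulating ribosomal-protein-like
  loci, which in real data sit orders of magnitude above the median.
  Counts are Poisson(FPKM × length_kb × depth/10⁶).
- **Tracks**: input is per-base Poisson noise at background rate 10 plus
  the negative-peak bumps; ChIP is the same noise plus Gaussian true-peak
  bumps (amplitude 150–250, sd 50 bp, centered 50–450 bp upstream of
  selected TSSs) and gene-body signal `coefficient × trueFPKM` (default
  coefficient 0.5) over the most-expressed cohort.  Both tracks declare a
  common nominal library total (background × genome size), modelling
  libraries sequenced to the same depth with amplitudes already in
  normalized units; noise variance therefore does not scale with planted
  signal (per-base Poisson noise, not read-level simulation).
- **True-peak genes** are drawn outside the hyper-ChIPable cohort: bona
  fide TF targets in the emulated study are moderately expressed, and a
  promoter peak merged into an adjacent high-expression gene body would
  conflate the two planted classes.
- **Negative peaks** are input-only Gaussian bumps (amplitude 100, sd
  50 bp) placed in free intergenic space, redrawn on collision — the
  minimal model of input-over-ChIP enrichment.
- **Caller emulation**: each of two callers detects each planted object
  with probability 0.9 per condition × replicate, reporting jittered
  (± 30 bp) boundaries; negative-peak loci also receive spurious calls,
  mirroring the observed co-occurrence of negative peaks among raw caller
  output.  Peak-caller internals are out of scope, so their output is
  emulated rather than reproduced.
- **Motif**: a copy of the 8-mer consensus TTCGGAAT (which contains the
  CGGA core), mutated per position at rate 0.1 to one of the three other
  bases, is written into the genome at each true-peak center on a random
  strand.

What the generator does *not* model: fragment-length effects, GC bias,
mappability, read-level sampling, condition-dependent binding strength, and
multi-span gene structure.  Passing the recovery tests therefore shows the
screen's logic is sound under the stated noise model, not that its default
thresholds transfer to arbitrary real datasets — on real data the
thresholds are config keys to be tuned against controls.

## Problem sizes used in validation

The recovery benchmarks run the full pipeline on 20 seeded instances of
the default study (≈ 7 million simulated bases each) and 20 seeded sampler
runs (20 × 200 bp sequences, 200 sweeps, 5 restarts); both complete in
about a minute on one CPU.  The FPKM unbiasedness check uses 2,000 genes.

## Determinism and IO contracts

Every randomized stage derives from an explicit integer seed (stage
generators use `default_rng([seed, stage_index])`).  Final outputs are
written to a temporary file and renamed, so interrupted runs leave no
partial artifacts; rerunning with the same config and seed is
byte-identical (timestamps only in the run log).  bedGraph writing uses
shortest-round-trip float formatting, so write-then-read reproduces values
bit-exactly.
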