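# Methods

## The mapping model

`sibsam` simulates and analyses bulk segregant analysis (BSA) and
introgression mapping (IM) experiments of the kind used for QTL mapping in
*Drosophila*-scale organisms: hundreds to thousands of offspring, pooled
sequencing, no individual genotyping.

Parental-strain ancestry (HIGH = the strain with the larger trait value) is
tracked along chromosomes X, 2 and 3 from the F1 generation onward.  Each
generation every offspring draws an independent random mother and father
from the previous generation.  Female gametes receive a Poisson-distributed
number of crossovers per chromosome with mean equal to the chromosome's
genetic length in Morgans, at uniform genetic positions; crossover
interference is not modeled.  Males do not recombine (as in *Drosophila*)
and transmit whole chromosome copies; the X follows standard X-linkage
(sons receive the mother's recombinant X, daughters add the father's X;
males are hemizygous, so X dosage counts a single allele).

Phenotypes are additive: a QTL with per-allele effect `f` adds `f` for every
HIGH allele carried, and Gaussian noise is added on top.  Two noise recipes
are used:

* **exploratory** (design study): SD equal to the design-mean trait value
  (e.g. five `f = 1` loci have mean score 5, hence noise SD 5);
* **inference** (pipeline and test scenarios): `0.5 × N(0, 1)` per
  individual.

QTL *strength* is the nominal variance fraction `s = f / (1 + f)`, i.e.
`f = s / (1 - s)`, anchored on the convention that a locus with `f = 1` is
nominally half the variance against the standard noise.  Note the literal
`0.5 × N(0,1)` noise has variance 0.25 while a codominant `f = 1` locus at
ancestry frequency ½ contributes 0.5, so `s` is a conventional label rather
than the realized variance fraction; the package keeps the literal recipe
because the inference pipeline is self-consistent (test and null
simulations use the same convention).  For the same reason, the design
study's five-QTL scenarios realize a much smaller genetic-variance fraction
than a naive reading of the recipe suggests; the recipe, not the fraction,
is what is implemented.

Selection takes phenotypic tails: BSA phenotypes only the final generation
(optionally females only) and sequences the top and bottom `⌊q·n⌋`
individuals as two pools; IM selects a single tail toward the non-backcross
strain every second generation starting at F2, mates selected individuals
to unlimited pure backcross-strain partners, and sequences the final
selected pool.  Sequencing draws `Binomial(depth, p)` ancestry-informative
reads per window per pool, where `p` is the pool's true ancestry frequency
at the window midpoint.  The BSA statistic is the ancestry difference
`a_d = freq_high − freq_low`; IM uses the ancestry proportion `a_p` of the
selected pool.  Under neutrality autosomal `a_p` follows the closed form
`0.5^(b+1)` after `b` backcross rounds (the X dilutes slightly differently
because males transmit no X to sons), which the tests verify.

## Two implementations, one model

A readable tract-level implementation (`AncestryChromosome`,
`recombine_gamete`, `breed_generation`, `phenotype`) represents each
chromosome copy as ancestry tracts and is convenient for small populations
and property tests.  The production engine (`sibsam._engine`) evaluates
ancestry exactly at window midpoints by crossover parity: since
interference is absent, the transmitted copy at a midpoint depends only on
the parity of crossovers to its left, so whole generations vectorize into
a few array operations.  At the evaluation points the two are
distributionally identical; the test suite checks both against the Haldane
map-function probability of recombinant ancestry between two positions.
QTL positions snap to the nearest window midpoint — the window is the
model's native resolution.

## Peak calling

Profiles are smoothed with a triangular moving average: the focal window
weighted `m + 1`, declining linearly to 1 at the `m`-th flanking window
(default `m = 4`), confined within chromosomes; at chromosome edges the
missing flank is dropped and weights renormalized (zero-padding would bias
edge values toward zero).  Empirical and simulated profiles always pass
through this same path.

A *primary peak* is the maximum of a maximal run of windows with smoothed
`a_d > 0`, kept if it exceeds `a_dt` (default 0.1, ties to the lowest
index).  *Secondary peaks* are found by scanning outward from the primary:
a recovery strictly greater than `v_t` (default 0.1) above the running
minimum opens a peak; a drop strictly greater than `v_t` below its running
maximum closes it (a peak still open when the run ends is recorded).  Each
secondary's deviation `v` is assigned tallest-first: the tallest secondary
on a side is judged against the lowest value between itself and the
primary; a shorter secondary between taller peaks takes the higher of its
two flanking valleys.  Reported secondaries satisfy `v > v_t`; secondaries
are confined to their primary's positive run.

## The inference pipeline

1. **Null stage.**  No-QTL replicates of the experiment (matched
   population size, generations, tails, depths, window map) yield a pooled
   distribution of primary-peak heights per genome scan.  For an empirical
   peak of height `h`, the enrichment is
   `e = (peaks ≥ h in the observed scan) / (mean peaks ≥ h per null scan)`
   and `P = 1/e` (capped at 1; a zero null frequency reports the ECDF
   resolution floor `1/(n_reps × observed count)` with a flag, never an
   exact zero).  Peaks with `P < 0.05` advance.
2. **Single-QTL stage.**  For each significant primary, replicates draw
   `s ~ Uniform(0, 1)`, simulate the population ancestries once, and place
   the QTL at the empirical peak window (ancestries are reused across peak
   positions; phenotyping, selection and read sampling are redrawn).  Each
   record keeps the genome-wide smoothed maximum, its position, and the
   maximum adjusted secondary deviation.  Rejection sampling accepts
   records with `|max a_d − empirical height| ≤ 0.025`; the strength
   posterior is the accepted-`s` (0.05, 0.5, 0.95) quantiles and the
   genomic CI the same quantiles of accepted peak positions re-centered on
   the empirical peak (simulated true-QTL→peak distances proxy empirical
   peak→true-QTL distances).  Accepted records whose maximum landed on
   another chromosome are excluded from the genomic CI and counted in the
   summary.  Secondary P-values are the fraction of *accepted* records
   whose maximum deviation is at least the observed one — conditioning on
   matched height integrates out the unknown primary strength.
3. **Cluster stage.**  A primary with significant secondaries is
   re-simulated as a cluster: cluster strength `~ Uniform(0,1)` apportioned
   by a symmetric Dirichlet(1,…,1) (uniform on the simplex), members fixed
   at the empirical peak windows.  Valley-bounded analysis zones (interior
   boundaries at the empirical minima between peaks, outer boundaries at
   the chromosome ends) score each member; a replicate is accepted only if
   every zone's local maximum matches its empirical height within 0.05.
   Member posteriors replace the single-stage estimates for the primary.

Numerical policies: quantiles use linear interpolation; if fewer than
`min_accept` (default 200) replicates are accepted, the tolerance doubles
once and the result is flagged; genomic CIs are clipped to the chromosome
but not to the analysis zone; all stage and replicate RNG streams derive
deterministically from one master seed via `SeedSequence((seed, stage,
replicate))`, so shards with disjoint replicate ranges merge exactly.
Tail selection breaks phenotype ties by stable individual index.

## Synthetic maps and study conditions

`make_synthetic_map` draws per-window genetic widths as symmetric Dirichlet
shares (concentration 3) of configurable chromosome lengths — defaults
approximate *D. melanogaster* (X ≈ 73 cM/23 Mb, 2 ≈ 108 cM/48 Mb,
3 ≈ 110 cM/52 Mb) — with jittered physical spans.  This reproduces
windows of variable genetic length without external data.  It does *not*
emulate strong recombination-rate structure of real chromosomes
(centromeric suppression piling many windows onto one genetic position),
empirical per-window depth variation, or polymorphism-density window
boundaries; conclusions about those features are outside what passing
tests show.

The focal test scenario is 1200 individuals for 16 generations, 600
females phenotyped, 10% tails, 1000 informative reads per window per pool;
scaled variants multiply population, phenotyped count and depth jointly.
Canonical single-QTL test positions are the classical map positions of
*tan* (X, 27.5 cM) and *ebony* (chromosome 3, 70.7 cM).  Desk-scale runs
use 150–200 windows per chromosome and hundreds to a thousand replicates
per stage, sizes chosen so the whole suite runs on one CPU in minutes;
because test replicates are always judged against null/prior simulations
from the same generator and map, calibration-type quantities (false-positive
rate, false-secondary rate, CI coverage) are approximately scale-free.

## Known limitations and observed deviations

* No crossover interference, epistasis, dominance beyond codominance,
  overlapping generations, or inadvertent laboratory selection.
* Strength estimates inherit the known winner's-curse (weak QTL) and
  saturation (very strong QTL) biases of peak-height rejection sampling.
* Under these study conditions the pipeline's detection power saturates:
  the null 95% genome-scan maximum (~0.19 at the focal scale) lies far
  below the typical smoothed peak height of a 20%-strength QTL
  (0.36 ± 0.06), so measured power is ~100% rather than the low-90s that
  noisier full-scale empirical data would give, and at 4× scale the null
  scan rarely exceeds `a_dt` at all.  The engine's selection
  response and null fluctuation scale both match independent analytic
  approximations (normal-theory selection differential; binomial pool
  variance), so this reflects the stated model rather than an
  implementation artifact — full-scale empirical maps with strong
  recombination/depth heterogeneity plausibly carry larger null extremes.
* The classification of two equal 15%-strength QTL 25 cM apart (secondary
  peak vs. merged single peak) is sensitive to map resolution: finer
  windows narrow the genetic span of the `m = 4` smoother and preserve the
  inter-peak dip, so the secondary-classification fraction rises from the
  mid-40s% at 150 windows per chromosome to the low-50s% at 200 (the
  acceptance script's resolution).
* Strength estimates when the residual variance comes from unlinked major
  QTL (rather than Gaussian noise) are inflated here somewhat more than
  under noisier full-scale conditions, for the same reason: a sharper
  height-to-strength mapping transfers the multi-QTL height excess
  directly into the posterior.
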