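# sibsam

Forward simulation and simulation-based inference for **bulk segregant
analysis (BSA)** QTL mapping, aimed at *Drosophila*-scale experiments where
hundreds to thousands of offspring (but not millions) can be bred and
phenotypic-extreme pools are sequenced in bulk.

Given a genome scan of the per-window **ancestry difference**

> *a_d* = (HIGH-pool ancestry fraction) − (LOW-pool ancestry fraction),

the package answers the questions a mapping experiment poses: *is this peak
a real QTL?*, *is that ragged shoulder a second linked QTL or noise?*,
*how strong is it and where is it, with what confidence?*  It does so by
simulating the experiment itself:

1. **Null stage** — no-QTL replicates of the exact experimental design give
   each primary peak a false-positive probability via the enrichment
   statistic *e* (peaks this tall per observed scan vs. per null scan),
   with *P* = 1/*e*.
2. **Single-QTL stage** — replicates with one QTL at the empirical peak
   window and strength *s* ~ Uniform(0,1) (per-allele effect
   *f* = *s*/(1−*s*)) feed a rejection-sampling (ABC) posterior: replicates
   whose maximum *a_d* matches the observed peak height within a tolerance
   yield the strength estimate (median, 0.05–0.95 quantiles), a genomic
   confidence interval, and P-values for secondary peaks.
3. **Cluster stage** — a primary with significant secondary peaks is
   re-simulated as a cluster of linked QTL (cluster strength apportioned
   uniformly on the simplex), accepting only replicates that match *every*
   member peak's height in its valley-bounded analysis zone.

A forward simulator (ancestry tracking, Poisson recombination, no male
crossing over, X-linkage with male hemizygosity, phenotypic tail selection,
binomial read sampling) powers all stages and doubles as an
experimental-design tool for comparing BSA with introgression mapping (IM)
and tuning generations, population size, selected fractions, and depth.

## Worked example

`examples/03_full_pipeline.py` simulates one experiment (600 individuals,
10 generations, 10% tails, depth 800) with a single QTL of strength
*s* = 0.35 on chromosome 2 at 60 cM, then runs the full pipeline:

```
true QTL: chromosome 2 at 60.0 cM, s = 0.35

primary peaks found: 1; significant: 1

peak P1 (primary, single stage)
  chrom 2 at 61.2 cM (bp ~27,405,236)
  P = 0.006667
  strength  s_hat = 0.374  (90% CI 0.316-0.416)
  location CI: 60.0-62.7 cM
  flags: pvalue_at_floor;tolerance_widened
```

Reading this: the scan's one primary peak is significant (no null replicate
produced a peak this tall, so *P* is reported at its resolution floor); the
posterior strength estimate 0.374 brackets the simulated 0.35, and the
genomic confidence interval of ~3 cM contains the true position.  The other
examples cover raw simulation (`01`), peak calling on linked QTL (`02`),
and the BSA-vs-IM design comparison (`04`).

## Command line

A thin CLI wraps the same functions:

```bash
sibsam make-map --windows 200 --seed 1 -o map.tsv
sibsam simulate --mode bsa --map map.tsv --config config.yaml -o profile.tsv
sibsam peaks --input profile.tsv -o peaks.tsv
sibsam null --input profile.tsv --config config.yaml --reps 1000 -o null.tsv
sibsam run  --input profile.tsv --config config.yaml --null-file null.tsv -o report.tsv
sibsam design-grid --grid grid.yaml --map map.tsv -o results.tsv
```

The window-table format is a TSV with columns
`chrom phys_start phys_end cm_start cm_end ad depth_high depth_low`
(IM tables carry `ap` and a single `depth`).  `sibsam null` shards are
mergeable with `sibsam merge` for parallel runs.

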