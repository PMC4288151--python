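# Methods

This note documents the models behind each stage of `oriterscan`, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Coordinate conventions

All coordinates are 0-based, half-open, on a single circular replicon.  A
segment with `start >= end` wraps through the coordinate origin; its
length is `(end - start) mod L`.  GFF3 input (1-based, inclusive) is
converted on read; BED and bedGraph are already half-open.  Genes are
represented as points by their midpoint `floor((start + end) / 2)` for
every positional statistic — symmetric and strand-free; strand is carried
in annotations but never used.  Bins tile `[0, L)` exactly; a short
terminal remainder bin is flagged partial and excluded from mode and Rc
statistics so it cannot bias either.

## Coverage model and the Rc statistic

Sequencing a population of DNA molecules in which a fraction *f* carries
a tandem duplication of segment *S* gives per-bin read counts that are
well approximated by independent Poisson draws: rate `d·(1 + f)` inside
*S* and `d` outside, where `d` is the single-copy mean depth per bin.
The generator samples exactly this — the per-bin count is a sufficient
statistic for every downstream estimator, so read-level simulation would
add cost without information.  (An optional read-start mode emits
individual positions, used to exercise the binning code.)  For a deletion
of the complement of *S* carried by a fraction *q*, the rate outside *S*
is `d·(1 − q)`.

Tracks are normalized by the mode of the per-bin count distribution: on
`y = log2(count + 1)` a fixed histogram with 0.1-wide cells anchored at 0
is built over full bins (optionally restricted to a stated segment), the
fullest cell wins — ties to the lower cell, making the estimate
deterministic — and its midpoint, back-transformed, is the mode factor.
With ~23,000 Poisson bins the peak is sharp and the estimate sits within
one cell of the true depth.  The `+1` pseudocount defines `log2(0)`.
Normalized values are `y − log2(mode_factor)` for *all* bins, so the
modal bin sits within half a cell of zero.

`Rc` is the ratio of arithmetic means of the *linear-scale* normalized
values (de-logged; means of logs would be biased low by noise) inside
versus outside the origin segment, partial bins excluded.  Under the
mixture model E[Rc] = 1 + f (duplication) or 1/(1 − q) (deletion), which
`infer_prevalence` inverts exactly, clipping to [0, 1].  An observed Rc
more than `tol = 0.02` below 1 raises an error — it means the
complementary segment is the amplified one and the caller should swap
orientation; the tolerance absorbs sampling noise on a variant-free
genome, where Rc scatters around 1 by ~0.005 at 250× depth.

A sample is called **pattern-positive** when Rc ≥ 1.5.  The threshold is
the bottom of the Rc range observed in duplication-carrying clones
(1.5–1.8) and is exposed as a flag; calls near the threshold should be
read with the sampling error of Rc in mind (negligible at full scale).

## Breakpoint detection

The duplication boundaries are sharp steps in the log2 track.  The
detector minimizes the total within-segment sum of squared deviations of
the log2 values over the two complementary circular segments — the
least-squares two-change-point fit of a piecewise-constant circular
signal — using prefix sums so each candidate split costs O(1):

* **Candidate mode** — exhaustive over all pairs of user-supplied
  coordinates (typically repeat-element positions such as the two
  identical IS2 copies that can mediate the duplication).
* **Free scan** — exhaustive over all bin-boundary pairs up to 5,000
  bins; above that, a two-stage scan (stride 10, then ±20-bin refinement
  at stride 1 around the coarse optimum) keeps the 23,000-bin full-scale
  search under a second without losing the optimum, since the SSE
  landscape is smooth at the coarse scale.

The free scan constrains each segment to at least 1% of the bins (and at
least 10): the target is a large segmental variant, and without the
constraint the split degenerates onto a handful of extreme-noise bins on
structure-less tracks (isolated spikes at repetitive loci would do the
same on real data).  With the constraint, a null track returns Rc ≈ 1.04
at desk scale and ≈ 1.01 at full scale; callers screen on Rc, so null
splits are inert.  Exact ties in the objective resolve to the smallest
first cut index, then the smallest second.  The higher-mean segment is
reported as the origin segment and Rc as its mean over the other's.

Planted-truth recovery: at f ≥ 0.5 and depth ≥ 100 the boundary step
(log2 1.5 ≈ 0.58) is ~4× the per-bin noise SD, and ≥ 95% of boundary
estimates land within ±1 bin of truth over 20 seeded replicates.

## Scenario likelihood ratio

If a variant is present in a fraction *p* of a population, the number *k*
of *n* sampled clones displaying the coverage pattern is Binomial(*n*,
*p*) (clones sampled independently; a clone displays the pattern iff it
descends from a carrier).  The evidence for duplication over deletion is
the ratio of the two binomial masses at the observed *k*, evaluated at
the prevalences that each explain the population-level Rc.  At the
calibration used throughout (n = 16, k = 3, p_dup = 0.25, p_del = 0.07)
the ratio is 2.78 — "about three times likelier".  The 25%/7% values are
treated as given calibration inputs.  Under this package's own deletion
forward model, Rc = 1.2 would invert to q ≈ 0.17 rather than 0.07; with
p_del = 0.17 the ratio would be smaller.  Both prevalences are therefore
parameters, not derived quantities, and the reported ratio is exactly the
calibrated one.

## Dosage-aware differential expression

Reads are assigned to genes by the first mapped base (half-open gene
intervals; coordinate-earlier gene wins where annotations overlap;
unassigned reads are reported, not discarded).

**Size factors.**  A segmental duplication inflates every count it
covers, so whole-library normalization would absorb part of the dosage
signal into the factor.  Instead, each sample's factor is the mode of its
per-gene count distribution over genes whose midpoint lies *outside* the
amplified segment, applied to the whole sample.  For strains without the
amplification the restriction is a no-op, so one rule serves every
sample.  The mode is located as the maximum of a Gaussian kernel density
(Scott bandwidth) on `log2(count + 1)`, evaluated on a 0.01-wide grid —
deterministic, and much more stable than a coarse histogram argmax:
per-gene count distributions are broad (the generator's default baseline
spreads gene means with log2 SD 1.0 around 500), so the fullest 0.1-cell
jitters by several cells between replicate libraries, which propagates
into spurious fold-change offsets of up to ~0.5; the KDE maximum holds
the median |log2FC| of planted-null non-amplified genes at ≤ 0.1 under a
1.8× dosage over 40% of the genome.  Factors are rescaled to geometric
mean 1: ratios (all the test depends on) are unchanged, and the 0.5
pseudocount in fold changes then acts on per-library-unit counts.

**Test.**  Replicates are pooled.  For gene *g* with group totals `x_A`,
`x_B` and effective sizes `S_A = Σ factors_A`, `S_B`:

    log2FC = log2((x_A/S_A + 0.5) / (x_B/S_B + 0.5))
    P      = two-sided exact binomial test of x_A out of x_A + x_B
             with p0 = S_A / (S_A + S_B)

A gene is called up iff log2FC ≥ 1 and P ≤ 10⁻⁵ (down symmetric); no
multiple-testing correction, mirroring the fixed-cutoff calling rule.
Zero-total genes get P = 1 and "ns".  The conditional binomial is exact
under Poisson counts (the generator's default); under overdispersed
(negative-binomial) counts it is anticonservative — the generator's NB
preset exists to demonstrate this, and real overdispersed data would need
a dispersion-aware model, which is deliberately out of scope.  Pooling
forfeits within-group replicate information; with the large planted
effects tested (|log2FC| = 2 at means ≥ 200) power exceeds 95%.

## Positional enrichment

For gene set G, observed counts are computed in sliding circular windows
(default sizes 100/200/400/800 kb, step half a window — enrichments have
no single natural scale).  The null shuffles the gene-id-to-location
assignment uniformly: locations are fixed, labels move, which is
equivalent to drawing |G| locations without replacement.  Per window,
P = (1 + #{null ≥ observed}) / (1 + N) with N = 1000 permutations by
default — never zero, valid at any N.  Windows are significant at
P < 0.01 with no cross-window correction (a Benjamini–Hochberg pass can
be applied to the returned P-values).  Because windows overlap and the
statistic is discrete, the empirical family-wide false-positive rate
under random gene sets sits slightly below the nominal level
(~0.003–0.03 at α = 0.01).

## Expression domains

Each gene is a vector of log-scale expression values over ~300
conditions.  Pairs are classified at PCC ≥ 0.5 / ≤ −0.5 (inclusive; a
1e-9 tolerance keeps exact-boundary pairs such as r = 0.5 inclusive
despite floating-point rounding).  Constant-valued genes have undefined
correlations; their pairs are excluded and reported.  Values are used as
provided — a compendium is already on a normalized log scale, and Pearson
correlation is invariant to per-gene affine transforms anyway.
Classification streams over gene blocks (standardized rows, block matrix
products), so memory stays at O(block²) regardless of gene count.

Classified pairs are accumulated into symmetric bin-pair count matrices
C (correlated) and A (anti-correlated) at 100-kb resolution, within-bin
pairs on the diagonal.  Domain extraction is this package's
formalization of reading block structure off such heatmaps: over all
ordered boundary pairs on the circular bin ring (exhaustive, O(B²)
partitions), maximize

    score = #(anti-correlated pairs crossing the partition)
          + #(correlated pairs not crossing it)

Ties go to the smallest first boundary, then the smallest second.  The
estimator is validated only on synthetic truth (planted two-domain
compendia; boundaries recovered within ±1 bin at loading a = 3, noise SD
1, 300 conditions).  On a null compendium (a = 0) fewer than 0.1% of
pairs classify at all and the partition of what remains carries no
signal; callers should check the classified-pair totals before
interpreting boundaries.

## Synthetic-data generator: scope and defaults

The generator's defaults are the study conditions used throughout the
tests: 4.6-Mb circular chromosome (23,000 bins of 200 nt) with a 2.0-Mb
origin-centred duplication arc between two repeat-boundary candidates
placed 1 Mb either side of the origin; mean depth 250 reads/bin;
compendium of 300 conditions with latent-factor loading 3 and residual
SD 1 (population cross-domain correlation −0.9, comfortably past the
−0.5 threshold at 300 conditions); count matrices with 2 replicates per
strain, Poisson dispersion, baseline mean 500 with log2 SD 1.0.  A
one-tenth-scale chromosome preset (460 kb) backs the fast unit tests;
full scale is used where an acceptance property states it.  All
generators are bit-reproducible given their seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: replication-gradient (multi-fork) coverage
profiles (the scan assumes a flat baseline; a strong gradient would need
detrending first), mappability and GC biases, repeat-induced coverage
spikes beyond what the minimum-segment constraint absorbs, overdispersed
RNA-seq counts (see above), correlated conditions or batch structure in
the compendium, and operon structure (neighbouring genes are independent
in the generator, while real within-operon pairs are strongly
co-expressed — on real data the correlated-pair diagonal is therefore
expected to be heavier).

## Default parameters

| Parameter | Default | Where |
|---|---|---|
| coverage bin width | 200 nt | `bin_coverage`, generators |
| mode histogram cell (coverage) | 0.1 on log2(count+1) | `mode_normalize` |
| KDE grid (size factors) | 0.01 on log2(count+1) | `restricted_mode_size_factors` |
| pattern threshold | Rc ≥ 1.5 | `classify_pattern`, CLI flag |
| minimum segment (free scan) | 1% of bins, ≥ 10 | `detect_breakpoints` |
| exhaustive-scan limit | 5,000 bins | `detect_breakpoints` |
| fold-change / P cutoffs | 2-fold, 10⁻⁵ | `differential_expression` |
| window sizes / step | 100–800 kb / half window | `positional_enrichment` |
| permutations / alpha | 1000 / 0.01 | `positional_enrichment` |
| PCC thresholds | ±0.5 inclusive | `classify_pairs` |
| domain bin size | 100 kb | `binpair_matrix` |

## Known limitations

* The deletion forward model covers coverage loss only in the deleted
  region of carrier molecules; no attempt is made to model growth-rate
  coupling between carriers and non-carriers within a culture.
* Single replicon only; no multi-chromosome or plasmid support.
* The exact binomial DE test is valid for Poisson-like counts only.
* Breakpoints are reported at bin resolution (200 nt by default).
* The two-domain partition assumes exactly two domains; more structured
  chromosomes would need a multi-change-point extension.
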