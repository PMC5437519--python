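# Methods

## The rainfall transform

For strictly increasing integer positions `p_1 < … < p_N` on one
chromosome, the transform emits the points `(x_i, y_i) = (p_{i+1},
log_b(p_{i+1} − p_i))` for `i = 1 … N−1`.  Conventions:

* **Log base.** `b = 10` by default, so y-values read directly as decades
  of inter-event distance (y = 2 ⇔ 100 bp).  Any base > 1 is accepted; for
  bases 10 and 2 the exact `log10`/`log2` routines are used so that exact
  powers map exactly (`log10(100) == 2.0`, with no last-ulp drift).
* **Coordinates.** 0-based, half-open (BED-native) throughout; 1-based
  dialects must be converted at the reader boundary.
* **Duplicates.** A repeated position would require `log 0`; duplicate
  positions on one chromosome are dropped at track construction (first
  occurrence kept) with a logged count, keeping the transform total.
* **Whole genome.** Chromosomes are laid end to end in the order of the
  chrom.sizes file (no karyotype re-sorting), each position shifted by the
  cumulative length of its predecessors.  No distance is ever computed
  across a chromosome boundary — such a gap has no biological meaning — so
  the first event of every chromosome is consumed silently.
* **Category of a point.** A point sits at the *later* event of its pair,
  so it carries the later event's label by default; `attach="earlier"` is
  available because either convention is defensible and published plots do
  not always say which they use.
* **Intensity readout.** `RainfallSeries.implied_intensity()` returns
  1 / mean inter-event distance, the Poisson intensity whose expected gap
  equals the observed mean.

## Grid discretization

A rendered plot is a W × H raster (default 1000 × 351, a typical journal
figure).  The x-domain `[0, total_length)` and y-domain `[0, y_max]` are
divided into equal half-open bins and each point is floored in:
`col = ⌊x / total_length · W⌋`, `row = ⌊y / y_max · H⌋`, both clamped into
the grid so the mapping is total (the single value `y = y_max` lands in the
top row).  Default `y_max` is `log10` of the longest chromosome — the
largest within-chromosome gap possible — and points above a user-supplied
`y_max` are clamped into the top row with a logged count.  Point count is
conserved for every grid.

## Congestion capacity

For each pixel row j the capacity profile reports

* `distinct_distances`: the number of integers `d ≥ 1` with
  `row(log10 d) = j`.  Row boundaries are found by binary search on the
  (monotone) row mapping, which is exact and avoids enumerating the ~10⁸
  representable distances of a genome-scale axis; on small grids it is
  verified against exhaustive enumeration.
* `min_distance`: the smallest such d (0 for rows representing none — kept
  explicitly so profiles of different grids are comparable).
* `max_overlap`: the worst-case number of events that can share one pixel,
  `⌊bin_width / min_distance⌋ + 1` with `bin_width = total_length / W` —
  i.e. events packed at the row's minimum distance inside a closed
  bin-width window.  This is a capacity bound, not an expectation; an
  expected-overlap statistic under a null is deliberately out of scope.

On a 1000 × 351 human-genome (hg19) grid the profile reproduces the
qualitative structure of a discretized rainfall axis: rows below ~52
represent zero or one integer distance each (exactly which low rows are
empty depends on the y-scaling constant, for which no published reference
value exists), while the top row represents ~1.3 × 10⁷ distinct distances
yet can hold only one event per x-pixel.

Realized congestion (`congestion_map`) reports pixels with count ≥ 2, the
maximum per-pixel count, the occupied fraction (saturation) and the
per-pixel count histogram.

## Band detection

`row_occupancy_bands` locates horizontal enrichment bands: rows are first
restricted to the *representable* subsequence (rows whose distance range
contains an integer — unrepresentable rows can never hold a point for any
data, so they neither break nor extend a band), their totals are
boxcar-smoothed (window: 1/50 of the representable rows), thresholded at a
fraction (default 10%) of the smoothed maximum, and maximal runs above
threshold become bands; runs narrower than the smoothing window are below
the resolution of the analysis and discarded.  The 10% threshold separates
the two modes of the default two-state hidden Markov model, whose
inter-mode valley sits at ~6% of the dominant mode's height while the
smaller mode peaks at ~25%.

## Simulators

All simulators are pure functions of `(parameters, seed)`; continuous
arrival positions are rounded to integers and the rare collisions resolved
by shifting +1 bp (at λ ≤ 0.1 this perturbs a fraction of order λ/2 of the
gaps by ≤ 1 bp and leaves the distance distribution materially unchanged).

* **HPP** (`simulate_hpp`): cumulative exponential(1/λ) spacings truncated
  at the region end.  Calibration: the count in a region of length L is
  Poisson(λL) and the mean gap is 1/λ; both are verified by replicate
  simulation and a Kolmogorov–Smirnov test on the pre-rounding gaps.
* **Piecewise NHPP** (`simulate_nhpp`): hotspot segments
  `(start, end, λ)` on a baseline intensity (0 = no background); each
  piece is an independent HPP, which for piecewise-constant intensity is
  distributionally equivalent to thinning.  Segment intensities may be
  given as mean inter-event distances instead (`from_mean_distances`,
  and `d<value>` in the CLI), since "inter-mutation value" is quoted both
  ways in the literature.
* **Hidden Markov point process** (`simulate_hmp`): per emitted event the
  latent state is drawn from the transition row of the current state, then
  one exponential gap at the new state's intensity.  Transitioning per
  event (rather than per base) is an interpretation choice; with the
  default equal-row matrix the two are indistinguishable at the level of
  the emitted gap mixture.  `HmpModel.two_state()` is the canonical
  hotspot model — λ_hot = 0.01/bp entered with probability 0.8,
  λ_background = 10⁻⁴/bp with probability 0.2 — whose gap histogram is
  bimodal with modes at the 10² and 10⁴ bp scales and whose stationary
  hot-state occupancy is 0.8.

## Frequency tracks

`bin_counts` counts events in fixed-size bins (default 3 Mbp, the
conventional genome-overview scale).  Default binning restarts at each
chromosome start so no bin mixes chromosomes; a global mode bins the
concatenated axis instead (and then refuses bedGraph export, which has no
faithful representation for boundary-straddling bins).  Counts are
conserved under any bin size and refine consistently (100 contiguous
30 kbp bins sum to their 3 Mbp bin).  `FrequencyTrack.zscores()`
standardizes bin counts against all bins; a short planted hotspot's
z-score falls monotonically as bins grow, which is the quantitative form
of the hotspot-dilution effect of coarse binning.

## Rendering policy

The acceptance surface of a rendered plot is its pixel-assignment table
(pixel → drawn category), not image bytes, which keeps comparisons free of
raster-encoder nondeterminism.  In the default *neutral* mode a pixel
receiving ≥ 2 distinct categories is drawn in a neutral color (black by
default; configured category colors may not collide with it), making the
table a pure function of each pixel's category multiset and hence
invariant to plotting order.  The *naive* mode reproduces last-drawn-wins
rendering under a configurable order (genomic, by-category, reversed,
as-given) to demonstrate the pitfall: between opposite category orders
every multi-category pixel flips.  The default glyph is a single pixel;
larger glyphs are supported but documented as an additional congestion
source.

## Synthetic data and its limits

The simulators generate the study conditions used throughout the tests:
uniform backgrounds (HPP), short intense hotspots (NHPP segments, e.g. 50
events in 1 kbp on a λ = 10⁻⁵/bp background over 300 Mbp), and two-scale
recurrent clustering (the two-state model above, simulated over 40 Mbp for
~1.9 × 10⁴ events).  They emulate the *spatial* statistics of mutation
data only: there is no sequence context, no substitution-type bias linked
to position, no copy-number or mappability structure, and category labels
are attached independently of position.  Passing tests therefore
demonstrate the correctness of the transform, discretization, congestion
accounting and rendering policy — not that real tumor genomes follow these
processes.  The bundled hg19 chromosome lengths serve whole-genome
examples without any download.

## Problem sizes and tolerances

Simulation-backed checks use 10⁴–2 × 10⁴ events per realization and up to
50 replicates, sizes at which every asserted quantity has a comfortable
margin: means are tested within 4–5 standard errors, the HPP grand mean
gap within 2% (its standard error at 5 × 10⁵ gaps is ~0.14%), per-state
intensity recovery within 10% (SE ≤ 2.3%), and distributional checks at
α = 0.01 on fixed seeds.  Exhaustive congestion oracles run on grids up to
10 × 10 over 10⁴ bp, where enumeration is instant; the analytic profile is
exact at any scale.
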