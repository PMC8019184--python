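# Methods

`migconn` is a virtual-ecologist toolkit: it simulates migratory
populations whose true connectivity is known by construction, applies the
spatial sampling (marking) designs that real tracking studies use, and
measures how the resulting Mantel correlation estimates deviate from the
scores of the populations they are meant to describe.

## The statistic

Migratory connectivity is quantified by the Mantel correlation: for a set
of individuals with known breeding and non-breeding locations, build the
pairwise-distance matrix for each season and take the Pearson correlation
over the n(n−1)/2 unordered off-diagonal pairs. r ≈ 1 means co-located
breeders stay co-located in the non-breeding season; r ≈ 0 means the
seasons mix. Significance, where requested, comes from a one-sided
permutation test: individuals of one matrix are relabelled by a
simultaneous row/column permutation, and p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1),
so p is never exactly zero. Point estimates in the experiment runners use
the statistic only; p-values play no role in the bias analyses.

Two references give each sampled estimate its meaning:

* **zone truth** — the score over *all* individuals whose breeding location
  lies inside the strict spatial extent of sampling (the *zone*: the
  sampling area itself, or the bounding rectangle of a set of discrete
  sites, or the union of the four patchy sampling areas);
* **global truth** — the score over the entire simulated population.

`bias_zone = r_sample − r_zone` isolates design-induced distortion within
the sampled space; `bias_global = r_sample − r_global` measures the cost of
extrapolating beyond it.

Whole-population truths over 10,000 individuals would need ~0.8 GB
matrices, so scores above 6,000 individuals stream over row blocks in two
passes (pair-distance means first, then centred second moments). Centring
before accumulation keeps the streamed correlation within 1e-12 of the
direct computation, which a test asserts.

## The simple population model

Breeding locations are uniform on a square range; migration translates
every individual a fixed distance due south and then displaces it by
`d ~ LogNormal(meanlog, sdlog=1)` in a direction uniform on the circle.
`meanlog ∈ {3, 5, 7}` gives the three named connectivity strengths
(high/medium/low): median displacements of ~20, ~148 and ~1097 map units.

The range side and shift are not identifiable from those parameters alone,
so they were calibrated against the model's intended operating point: with
side = 5600 and shift = 11,200 (disjoint seasonal ranges), the
whole-population Mantel score of the weakest level is ≈ 0.33 and the
replicate SD of 100 samples of 10 individuals is ≈ 0.23. Both are
config-exposed (`population.breeding_rect`, `population.shift_south`).

A property of this model worth knowing: the LogNormal(7, 1) tail puts
roughly 20 of every 10,000 individuals at displacements of 25,000–60,000
units — several times the migration distance itself. These few extreme
migrants dominate the non-breeding distance variance, so the replicate SD
of Mantel estimates decays more slowly than 1/√n between sample sizes of
10 and 1,000 (≈ 0.24 → ≈ 0.04 at the weakest connectivity). Capping the
top 0.2 % of displacements would push SD(1,000) below 0.025, but no such
truncation is part of the model, so none is applied.

## Sampling designs

All designs constrain *where marking happens* (breeding locations only);
non-breeding locations are never constrained — that asymmetry is the
mechanism behind every bias the package measures. Individuals are always
drawn uniformly without replacement from the pool breeding inside the
design footprint (no per-site quotas), with 200 tracked per study.

* **Area**: one centred square; default sides 2800 / 3640 / 4480. The
  smallest side is half the range: below ~2500 units the medium-strength
  zone truth collapses further than the weak level's bounded headroom
  (its global truth is only 0.33), which would invert the expected
  severity-vs-connectivity ordering, and the zone would hold too few
  individuals for stable truths.
* **Spread**: nine 560-unit sites on a 3×3 grid, centre spacings 616 /
  1400 / 2352 (total sampled area constant). The zone is the grid's
  bounding rectangle — the contiguous extent, not the union of boxes.
* **Patchy**: one square area centred in each of four breeding patches,
  sides 0.25 / 0.5 / 0.75 of the patch side.
* **Sites (realistic ranges)**: a 15×15 grid over the breeding range; the
  20 highest-count cells (row-major tie-break) form the site pool; each
  study uses k ∈ 3..20 of them, re-drawn per replicate, with a bounded
  retry (fresh sub-seed) if an unlucky selection holds fewer than 200
  individuals.

## Patchy populations

Four equal patches (side 0.4 × range side) sit at the corners of the
breeding range; 2,500 individuals per patch migrate as above and only those
reaching one of four retention regions (squares of 0.4 × range side centred
on the shifted patch centres) are kept, delimiting sub-populations in both
seasons. Patch size was chosen so that patch separation is comparable to
the weak-level displacement scale: that is the regime where individuals can
reach a neighbouring patch's region and sampling design genuinely changes
the estimate; with far-separated patches the patch-to-region correspondence
is deterministic and every design returns the same block-structure score.

Because the global-truth bias of a patchy study is in large part a property
of *which population got simulated* (the zone holds only a few hundred
individuals), the patchy runner spreads its 100 replicate studies per cell
over 10 independently regenerated populations (10 samples each) rather than
reusing one; each study is then a fresh dataset plus a fresh sample. The
contiguous-scenario runners keep a single population per connectivity level
so that their replicate spread reflects sampling effects alone. Both
choices are config-exposed (`patchy.n_populations`).

## Realistic ranges

Three synthetic GeoJSON range pairs are bundled (`wide`, `compact`,
`elongated` — invented geometries, not replicas of any species' range).
For each season: a stationary Gaussian random field with squared-exponential
covariance (correlation length 10 cells, variance 100) is simulated by
circulant embedding (FFT) on a 100×100 grid over the range's bounding box,
min–max scaled to [0, 1], and zeroed outside the polygon (cells overlapping
the polygon by < 0.1 % of their area are treated as outside so every
positive-weight cell can host points). A constant field — the zero-variance
limit — gets weight 0.5 everywhere, equivalent to any constant under
proportional sampling. 50,000 individuals (10,000 in the scaled-down test
configuration) are placed cell-proportionally, uniform within each cell's
polygon intersection by rejection sampling.

Seasons are linked by **longitudinal-rank matching**: both point sets are
ranked by longitude (ties: latitude, then index) and each breeding
individual, visited in random order, draws uniformly among the
still-unassigned non-breeding points whose rank lies within ± bandwidth of
its own (clamped at the ends). Bandwidths 1,000 / 13,000 / 25,000 per
50,000 individuals give the high/medium/low connectivity levels; scaled
runs keep the bandwidth:n ratios. When the sequential draw strands an
individual whose window is fully consumed, the partial assignment is
repaired by a Kuhn-style augmenting path that stays inside every
individual's window. The identity pairing is always feasible, so by the
exchange property of bipartite matchings such a path always exists; repair
is preferred over restarting because at small bandwidths the naive greedy
strands someone almost surely, making restarts useless, while repairs touch
only a handful of assignments.

## Determinism and seeds

Every runner derives all randomness from one master seed through
`numpy.random.SeedSequence` spawn keys of the form
(scenario, connectivity index, level index, replicate); the derived
per-replicate seed (kept below 2³¹) is stored in each output record, so any
single replicate is reproducible in isolation. Identical invocations are
byte-identical, including the CSV outputs of the command-line layer
(provenance sidecars carry no timestamps).

## Numerical and degenerate-case choices

* Rectangle containment uses closed intervals (boundary points are inside);
  a measure-zero choice fixed for determinism.
* A distance matrix with zero off-diagonal variance raises
  `DegenerateDistanceError` rather than returning 0, so degenerate
  replicates can never silently contaminate a summary.
* Haversine distances (for geographic coordinates) use the IUGG mean Earth
  radius and return kilometres; all bundled fixtures are planar.
* Mantel scores need n ≥ 3; truth scores raise if a zone holds fewer than
  3 breeders.
* Replicate summaries use the n−1 denominator for SDs; single-replicate
  cells yield NaN SDs rather than an error.

## What the generator does and does not emulate

The synthetic populations isolate *sampling* effects: placement is uniform
(or GRF-clustered for realistic ranges), every marked individual is tracked
successfully, and there is no location error, tag loss, demographic
structure, or abundance-biased catchability. Passing tests therefore show
how sampling design alone moves Mantel estimates under known conditions;
they do not bound the additional biases real studies face (non-random
catchability, differential tag recovery, location uncertainty), all of
which are out of scope here.

## Test scaling

The slower end-to-end tests run at reduced problem sizes chosen to keep the
full suite in the tens of minutes while preserving each pattern's
signal-to-noise: zone-size monotonicity uses populations of 3,000 (10
replicate populations per level); the realistic-range experiment uses
10,000 individuals per fixture, 30 replicates per cell, and k ∈ {3, 4, 5, 20};
all other experiments run at full study scale (N = 10,000, 100 replicates).
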