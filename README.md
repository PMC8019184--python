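# migconn

**Sampling-design bias in Mantel-based migratory connectivity estimates.**

Tracking studies quantify *migratory connectivity* — the degree to which
individuals that breed near each other also spend the non-breeding season
near each other — with the Mantel correlation: the Pearson correlation
between the pairwise distances of sampled individuals in one season and
their pairwise distances in another,

    r = corr( {d_breed(i,j)}, {d_nonbreed(i,j)} )  over unordered pairs i<j.

But where the marked individuals come from constrains the observable
breeding distances while leaving non-breeding distances untouched, so the
estimate depends on the spatial extent and configuration of sampling, not
just on the animals' ecology. `migconn` is a virtual-ecologist simulation
toolkit for movement ecologists and study designers that makes this bias
measurable: it generates migratory populations with known, tunable
connectivity, applies realistic marking designs (single study areas, 3×3
site grids of varying spread, per-patch areas in patchy populations, and
k-of-20 high-density study sites over realistic range polygons), and
compares every sampled score against two truths — the score of everyone
inside the *zone* of sampling, and the score of the whole population.

## Worked example

Simulate three populations on the default geometry and score their true
connectivity (`examples/01_simulate_population.py`):

```text
  high connectivity (displacement meanlog 3.0): r = 0.999
medium connectivity (displacement meanlog 5.0): r = 0.964
   low connectivity (displacement meanlog 7.0): r = 0.322
```

Each individual migrates a fixed distance due south plus a lognormal random
displacement; a larger displacement scale mixes the seasons and the
whole-population Mantel score falls.

Now apply two marking designs to the weakest population
(`examples/03_sampling_design_bias.py`, 25 replicate studies of 200
tracked individuals each):

```text
=== nine-site 3x3 grids (increasing spread) ===
 level  mean_r  mean_bias_zone  mean_bias_global
   low  +0.031          +0.003            -0.298
medium  +0.227          +0.063            -0.102
  high  +0.391          +0.085            +0.062
```

`bias_zone` is the error with respect to the individuals the design could
have caught; `bias_global` the error of extrapolating to the whole
population. Widely spaced site grids *overestimate* even their own zone's
connectivity (+0.085 at high spread) because the gaps between sites
oversample large breeding pairwise distances, while any spatially
restricted design *underestimates* population-scale connectivity (−0.30 at
low spread here).

The other examples cover the permutation Mantel test, realistic
range-polygon populations built from Gaussian-random-field density
surfaces linked by longitudinal-rank matching, and the k-of-20 discrete
site experiment. A thin CLI wraps the same pipeline:

```bash
migconn simulate --n 10000 --meanlog 7 --seed 1 --out pop.csv
migconn mantel pop.csv
migconn fixtures --out-dir fixtures/      # bundled range polygons + example config
migconn experiment --config fixtures/example_config.yaml --out-dir results/
```

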