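"""Replicate experiment runners.

Each runner simulates many independent "studies" of the same underlying
population and records, per replicate, the sampled Mantel score alongside
two truth references:

* ``r_zone``   — the score over *all* individuals breeding inside the strict
  spatial extent of sampling (the zone), and
* ``r_global`` — the score over the entire simulated population.

The derived quantities ``bias_zone = r_sample - r_zone`` and
``bias_global = r_sample - r_global`` separate two distinct failure modes:
a sampling design can misestimate connectivity even for the individuals it
could have caught (zone bias), and inference can break down when a locally
unbiased score is extrapolated to the wider population (global bias).

One population is generated per connectivity level and reused across
replicates, so between-replicate variation reflects sampling alone.  All
randomness derives from a single master seed through ``numpy``
``SeedSequence`` spawn keys; the per-replicate seed is stored in each
record, making any single replicate reproducible in isolation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import (
    DEFAULT_AREA_SIDES,
    DEFAULT_N_SAMPLE,
    DEFAULT_SPREAD_SPACINGS,
    AreaDesign,
    SiteDesign,
    default_area_designs,
    default_spread_designs,
    sample_area,
    sample_patchy,
    sample_sites,
    sample_spread_grid,
    select_top_density_cells,
)
from .geometry import Rect, bounding_rect
from .mantel import global_truth_score, score_sample, zone_truth_score
from .population import (
    CONNECTIVITY_MEANLOG,
    DEFAULT_BREEDING_RECT,
    DEFAULT_SHIFT_SOUTH,
    MigrationParams,
    PairedPopulation,
    apply_migration,
    default_patchy_layout,
    simulate_breeding_uniform,
    simulate_patchy_population,
)
from .ranges import (
    DEFAULT_BANDWIDTHS,
    GaussianFieldParams,
    RankMatchParams,
    RangePolygon,
    density_surface_for_range,
    distribute_individuals,
    load_fixture,
    match_by_longitudinal_rank,
)

__all__ = [
    "derive_seed",
    "make_population",
    "run_area_experiment",
    "run_spread_experiment",
    "run_sample_size_experiment",
    "run_patchy_experiment",
    "run_realistic_experiment",
    "summarize_replicates",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "scenario",
    "connectivity",
    "level",
    "replicate",
    "r_sample",
    "r_zone",
    "r_global",
    "bias_zone",
    "bias_global",
    "n_sample",
    "k_sites",
    "site_centroid_mean_dist",
    "seed",
]

DEFAULT_SAMPLE_SIZES = (10, 50, 100, 1000, 2500, 5000)
DEFAULT_PATCHY_AREA_FRACS = {"small": 0.25, "medium": 0.5, "large": 0.75}


def derive_seed(master_seed: int, *key) -> int:
    """Counter-based sub-seed: hash of (master seed, structured key).

    String key parts are folded to stable integers so the spawn key is
    reproducible across sessions; the result is kept below 2**31.
    """
    ikey = tuple(
        int.from_bytes(k.encode(), "little") % (2**31) if isinstance(k, str) else int(k)
        for k in key
    )
    ss = np.random.SeedSequence(master_seed, spawn_key=ikey)
    return int(ss.generate_state(1)[0] % 2**31)


def make_population(
    n: int,
    disp_meanlog: float,
    seed: int,
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    shift_south: float = DEFAULT_SHIFT_SOUTH,
    disp_sdlog: float = 1.0,
) -> PairedPopulation:
    """Uniform breeding placement plus the shift-and-scatter migration."""
    s_breed = derive_seed(seed, "breed")
    s_mig = derive_seed(seed, "migrate")
    pop = simulate_breeding_uniform(n, breeding_rect, s_breed)
    return apply_migration(
        pop,
        MigrationParams(shift_south, disp_meanlog, disp_sdlog, s_mig),
    )


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RECORD_COLUMNS]


def run_area_experiment(
    master_seed: int = 0,
    n: int = 10_000,
    connectivity: Mapping[str, float] = CONNECTIVITY_MEANLOG,
    area_sides: Sequence[float] = DEFAULT_AREA_SIDES,
    n_sample: int = DEFAULT_N_SAMPLE,
    n_replicates: int = 100,
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    shift_south: float = DEFAULT_SHIFT_SOUTH,
) -> pd.DataFrame:
    """Single-area sampling with three (by default) area sizes."""
    designs = default_area_designs(breeding_rect, tuple(area_sides), n_sample)
    rows = []
    for ci, (cname, meanlog) in enumerate(connectivity.items()):
        pop = make_population(
            n, meanlog, derive_seed(master_seed, "pop", ci), breeding_rect, shift_south
        )
        r_global = global_truth_score(pop)
        for li, (lname, design) in enumerate(designs.items()):
            r_zone = zone_truth_score(pop, design.area)
            for rep in range(n_replicates):
                seed = derive_seed(master_seed, "area", ci, li, rep)
                res = sample_area(pop, design, seed)
                r = score_sample(pop, res.ids)
                rows.append(
                    dict(
                        scenario="area",
                        connectivity=cname,
                        level=lname,
                        replicate=rep,
                        r_sample=r,
                        r_zone=r_zone,
                        r_global=r_global,
                        bias_zone=r - r_zone,
                        bias_global=r - r_global,
                        n_sample=design.n_sample,
                        seed=seed,
                    )
                )
    return _finish(rows)


def run_spread_experiment(
    master_seed: int = 0,
    n: int = 10_000,
    connectivity: Mapping[str, float] = CONNECTIVITY_MEANLOG,
    spacings: Sequence[float] = DEFAULT_SPREAD_SPACINGS,
    n_sample: int = DEFAULT_N_SAMPLE,
    n_replicates: int = 100,
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    shift_south: float = DEFAULT_SHIFT_SOUTH,
) -> pd.DataFrame:
    """Nine-site 3x3 grids with three (by default) spacings."""
    designs = default_spread_designs(breeding_rect, tuple(spacings), n_sample=n_sample)
    rows = []
    for ci, (cname, meanlog) in enumerate(connectivity.items()):
        pop = make_population(
            n, meanlog, derive_seed(master_seed, "pop", ci), breeding_rect, shift_south
        )
        r_global = global_truth_score(pop)
        for li, (lname, design) in enumerate(designs.items()):
            r_zone = zone_truth_score(pop, bounding_rect(design.sites))
            for rep in range(n_replicates):
                seed = derive_seed(master_seed, "spread", ci, li, rep)
                res = sample_spread_grid(pop, design, seed)
                r = score_sample(pop, res.ids)
                rows.append(
                    dict(
                        scenario="spread",
                        connectivity=cname,
                        level=lname,
                        replicate=rep,
                        r_sample=r,
                        r_zone=r_zone,
                        r_global=r_global,
                        bias_zone=r - r_zone,
                        bias_global=r - r_global,
                        n_sample=design.n_sample,
                        site_centroid_mean_dist=res.site_centroid_mean_dist,
                        seed=seed,
                    )
                )
    return _finish(rows)


def run_sample_size_experiment(
    master_seed: int = 0,
    n: int = 10_000,
    connectivity: Mapping[str, float] = CONNECTIVITY_MEANLOG,
    sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    n_replicates: int = 100,
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    shift_south: float = DEFAULT_SHIFT_SOUTH,
) -> pd.DataFrame:
    """Whole-range random samples of increasing size.

    Sampling covers the entire breeding range, so the zone truth and the
    global truth coincide; precision (the SD of scores over replicates) is
    the quantity of interest here.
    """
    rows = []
    for ci, (cname, meanlog) in enumerate(connectivity.items()):
        pop = make_population(
            n, meanlog, derive_seed(master_seed, "pop", ci), breeding_rect, shift_south
        )
        r_global = global_truth_score(pop)
        for li, size in enumerate(sizes):
            design = AreaDesign(breeding_rect, n_sample=int(size))
            for rep in range(n_replicates):
                seed = derive_seed(master_seed, "size", ci, li, rep)
                res = sample_area(pop, design, seed)
                r = score_sample(pop, res.ids)
                rows.append(
                    dict(
                        scenario="sample_size",
                        connectivity=cname,
                        level=str(int(size)),
                        replicate=rep,
                        r_sample=r,
                        r_zone=r_global,
                        r_global=r_global,
                        bias_zone=r - r_global,
                        bias_global=r - r_global,
                        n_sample=int(size),
                        seed=seed,
                    )
                )
    return _finish(rows)


def run_patchy_experiment(
    master_seed: int = 0,
    connectivity: Mapping[str, float] = CONNECTIVITY_MEANLOG,
    area_fracs: Mapping[str, float] = DEFAULT_PATCHY_AREA_FRACS,
    per_patch_n: int = 2500,
    n_sample: int = DEFAULT_N_SAMPLE,
    n_replicates: int = 100,
    n_populations: int = 10,
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    shift_south: float = DEFAULT_SHIFT_SOUTH,
) -> pd.DataFrame:
    """Four-patch populations sampled with one area centred in each patch.

    ``area_fracs`` gives the sampling-area side as a fraction of the patch
    side for each named size level.  The zone is the union of the four
    areas.  Unlike the contiguous scenarios, the global-truth bias of a
    patchy study is dominated by which particular population got simulated,
    so the ``n_replicates`` studies per cell are spread over
    ``n_populations`` independently regenerated populations (each study =
    fresh dataset + fresh sample); every population is reused across the
    area-size levels.
    """
    if n_replicates % n_populations:
        raise ValueError("n_replicates must be a multiple of n_populations")
    reps_per_pop = n_replicates // n_populations
    layout = default_patchy_layout(breeding_rect, shift_south, per_patch_n=per_patch_n)
    area_levels = {
        lname: tuple(
            Rect.centred_square(*p.centroid, frac * p.width)
            for p in layout.breed_patches
        )
        for lname, frac in area_fracs.items()
    }
    rows = []
    for ci, (cname, meanlog) in enumerate(connectivity.items()):
        for pi in range(n_populations):
            pop = simulate_patchy_population(
                layout,
                MigrationParams(
                    shift_south, meanlog, 1.0, derive_seed(master_seed, "mig", ci, pi)
                ),
                seed=derive_seed(master_seed, "patchpop", ci, pi),
            )
            r_global = global_truth_score(pop)
            for li, (lname, areas) in enumerate(area_levels.items()):
                r_zone = zone_truth_score(pop, areas)
                for rep in range(reps_per_pop):
                    seed = derive_seed(master_seed, "patchy", ci, pi, li, rep)
                    res = sample_patchy(pop, areas, n_sample, seed)
                    r = score_sample(pop, res.ids)
                    rows.append(
                        dict(
                            scenario="patchy",
                            connectivity=cname,
                            level=lname,
                            replicate=pi * reps_per_pop + rep,
                            r_sample=r,
                            r_zone=r_zone,
                            r_global=r_global,
                            bias_zone=r - r_zone,
                            bias_global=r - r_global,
                            n_sample=n_sample,
                            seed=seed,
                        )
                    )
    return _finish(rows)


def run_realistic_experiment(
    fixture: str | tuple[RangePolygon, RangePolygon],
    master_seed: int = 0,
    n: int = 50_000,
    bandwidths: Mapping[str, int] = DEFAULT_BANDWIDTHS,
    ks: Sequence[int] = tuple(range(3, 21)),
    n_sample: int = DEFAULT_N_SAMPLE,
    n_replicates: int = 100,
    field_params: GaussianFieldParams | None = None,
    site_grid: tuple[int, int] = (15, 15),
) -> pd.DataFrame:
    """k-of-20 discrete-site sampling over a realistic range pair.

    One breeding and one non-breeding point set are generated once per
    fixture; each bandwidth re-links them into a population of different
    connectivity.  The site pool is the 20 highest-density cells of a
    coarse grid over the breeding range; each replicate picks k sites at
    random and samples 200 individuals from their union.  Zone truths are
    not computed here (the reference of interest is the whole-population
    score, reported as ``r_global``); ``r_zone`` is left as NaN.
    """
    breed_range, nonbreed_range = (
        load_fixture(fixture) if isinstance(fixture, str) else fixture
    )
    fname = fixture if isinstance(fixture, str) else "custom"
    fp = field_params or GaussianFieldParams()
    s_build = derive_seed(master_seed, "realistic", fname)
    surf_b = density_surface_for_range(
        breed_range, GaussianFieldParams(fp.grid_nx, fp.grid_ny, fp.autocorr_range, fp.magnitude, derive_seed(s_build, "fb"))
    )
    surf_w = density_surface_for_range(
        nonbreed_range, GaussianFieldParams(fp.grid_nx, fp.grid_ny, fp.autocorr_range, fp.magnitude, derive_seed(s_build, "fw"))
    )
    breed_pts = distribute_individuals(surf_b, breed_range, n, derive_seed(s_build, "pb"))
    nonbreed_pts = distribute_individuals(surf_w, nonbreed_range, n, derive_seed(s_build, "pw"))
    pool = select_top_density_cells(breed_pts, breed_range.bbox, *site_grid, k=20)

    rows = []
    for bi, (bname, bw) in enumerate(bandwidths.items()):
        pop = match_by_longitudinal_rank(
            breed_pts, nonbreed_pts, RankMatchParams(int(bw), derive_seed(s_build, "match", bi))
        )
        r_global = global_truth_score(pop)
        for k in ks:
            for rep in range(n_replicates):
                seed = derive_seed(master_seed, "sites", fname, bi, int(k), rep)
                design = SiteDesign(pool, int(k), n_sample, seed)
                res = sample_sites(pop, design)
                r = score_sample(pop, res.ids)
                rows.append(
                    dict(
                        scenario=f"realistic:{fname}",
                        connectivity=bname,
                        level=f"k={int(k):02d}",
                        replicate=rep,
                        r_sample=r,
                        r_global=r_global,
                        bias_global=r - r_global,
                        n_sample=n_sample,
                        k_sites=int(k),
                        site_centroid_mean_dist=res.site_centroid_mean_dist,
                        seed=seed,
                    )
                )
    return _finish(rows)


def summarize_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and SD (ddof=1) of scores and mean biases.

    Cells are (scenario, connectivity, level) groups; an empty input is an
    error, and single-replicate cells yield NaN standard deviations.
    """
    if len(records) == 0:
        raise ValueError("no replicate records to summarise")
    grouped = records.groupby(["scenario", "connectivity", "level"], sort=False)
    out = grouped.agg(
        mean_r=("r_sample", "mean"),
        sd_r=("r_sample", lambda s: s.std(ddof=1)),
        mean_bias_zone=("bias_zone", "mean"),
        mean_bias_global=("bias_global", "mean"),
        n_replicates=("r_sample", "size"),
    ).reset_index()
    return out
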