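"""Spatial sampling (marking) designs.

Every design answers the same question: *where* on the breeding range are
individuals caught and tagged?  Four regimes are covered:

* a single rectangular area of varying size (``AreaDesign``),
* nine equal sites on a 3 x 3 grid whose spacing varies (``SpreadDesign``),
* one area centred within each of four breeding patches (patchy sampling),
* k discrete sites drawn from a pool of the 20 highest-density grid cells
  (``SiteDesign``, used with realistic range simulations).

In all cases individuals are drawn uniformly without replacement from the
pool of individuals whose *breeding* location falls inside the design
footprint; non-breeding locations are never constrained — that asymmetry is
the core mechanism behind sampling-design bias in Mantel connectivity
estimates.

The *zone* recorded with each sample is the strict spatial extent of
sampling: the area itself for a single-area design, and the axis-aligned
bounding rectangle of the sites for multi-site designs (the contiguous
extent, not the bare union of boxes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .geometry import Rect, bounding_rect, union_contains
from .population import DEFAULT_BREEDING_RECT, PairedPopulation

__all__ = [
    "AreaDesign",
    "SpreadDesign",
    "SiteDesign",
    "SampleResult",
    "InsufficientIndividualsError",
    "sample_area",
    "sample_spread_grid",
    "sample_patchy",
    "select_top_density_cells",
    "sample_sites",
    "mean_site_centroid_distance",
    "default_area_designs",
    "default_spread_designs",
]

#: individuals tracked per simulated study
DEFAULT_N_SAMPLE = 200

#: centred-square side lengths for the small / medium / large area scenarios
#: (map units, on the calibrated 5600-unit breeding range)
DEFAULT_AREA_SIDES = (2800.0, 3640.0, 4480.0)

#: 3x3 spread-grid geometry: site side, and centre-to-centre spacings for the
#: low / medium / high spread scenarios
DEFAULT_SPREAD_SITE_SIDE = 560.0
DEFAULT_SPREAD_SPACINGS = (616.0, 1400.0, 2352.0)


class InsufficientIndividualsError(RuntimeError):
    """The design footprint holds fewer individuals than requested."""

    def __init__(self, available: int, requested: int):
        self.available = available
        self.requested = requested
        super().__init__(
            f"design footprint holds {available} individuals, "
            f"but {requested} were requested"
        )


@dataclass(frozen=True)
class AreaDesign:
    area: Rect
    n_sample: int = DEFAULT_N_SAMPLE


@dataclass(frozen=True)
class SpreadDesign:
    """Nine equal sites on a regular 3 x 3 grid."""

    sites: tuple[Rect, ...]
    spacing: float
    n_sample: int = DEFAULT_N_SAMPLE

    def __post_init__(self) -> None:
        if len(self.sites) != 9:
            raise ValueError("spread design needs exactly 9 sites")
        areas = [s.area for s in self.sites]
        if not np.allclose(areas, areas[0]):
            raise ValueError("spread sites must be equal-sized")

    @classmethod
    def centred_grid(
        cls,
        spacing: float,
        site_side: float = DEFAULT_SPREAD_SITE_SIDE,
        breeding_rect: Rect = DEFAULT_BREEDING_RECT,
        n_sample: int = DEFAULT_N_SAMPLE,
    ) -> "SpreadDesign":
        if spacing < site_side:
            raise ValueError("spacing below site side would overlap sites")
        cx, cy = breeding_rect.centroid
        sites = tuple(
            Rect.centred_square(cx + ix * spacing, cy + iy * spacing, site_side)
            for iy in (-1, 0, 1)
            for ix in (-1, 0, 1)
        )
        return cls(sites, spacing, n_sample)


@dataclass(frozen=True)
class SiteDesign:
    """k sites drawn at random from a fixed pool of 20 candidate sites."""

    pool: tuple[Rect, ...]
    k: int
    n_sample: int = DEFAULT_N_SAMPLE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pool) != 20:
            raise ValueError("site pool must hold exactly 20 candidate sites")
        if not (3 <= self.k <= 20):
            raise ValueError("k must lie in 3..20")


@dataclass
class SampleResult:
    """Outcome of one simulated marking study."""

    design: str
    ids: np.ndarray
    zone: Rect | tuple[Rect, ...]
    sites: tuple[Rect, ...] = field(default_factory=tuple)
    site_centroid_mean_dist: float | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("sampled ids must be unique")


def _draw_from_mask(
    pop: PairedPopulation, mask: np.ndarray, n_sample: int, rng: np.random.Generator
) -> np.ndarray:
    candidates = pop.ids[mask]
    if len(candidates) < n_sample:
        raise InsufficientIndividualsError(len(candidates), n_sample)
    return rng.choice(candidates, size=n_sample, replace=False)


def sample_area(pop: PairedPopulation, design: AreaDesign, seed: int = 0) -> SampleResult:
    """Uniform draw of ``n_sample`` individuals breeding inside one area."""
    rng = np.random.default_rng(seed)
    mask = design.area.contains(pop.breed_xy)
    ids = _draw_from_mask(pop, mask, design.n_sample, rng)
    return SampleResult(design="area", ids=ids, zone=design.area, sites=(design.area,))


def sample_spread_grid(
    pop: PairedPopulation, design: SpreadDesign, seed: int = 0
) -> SampleResult:
    """Pooled uniform draw across the nine grid sites.

    The 200 individuals are drawn from the union of sites without per-site
    quotas; the zone is the bounding rectangle of the grid.
    """
    rng = np.random.default_rng(seed)
    mask = union_contains(design.sites, pop.breed_xy)
    ids = _draw_from_mask(pop, mask, design.n_sample, rng)
    return SampleResult(
        design="spread",
        ids=ids,
        zone=bounding_rect(design.sites),
        sites=design.sites,
        site_centroid_mean_dist=mean_site_centroid_distance(design.sites),
    )


def sample_patchy(
    pop: PairedPopulation,
    areas: tuple[Rect, Rect, Rect, Rect],
    n_sample: int = DEFAULT_N_SAMPLE,
    seed: int = 0,
) -> SampleResult:
    """Pooled uniform draw across one sampling area per breeding patch."""
    if len(areas) != 4:
        raise ValueError("patchy sampling uses exactly 4 areas")
    rng = np.random.default_rng(seed)
    mask = union_contains(areas, pop.breed_xy)
    ids = _draw_from_mask(pop, mask, n_sample, rng)
    return SampleResult(
        design="patchy",
        ids=ids,
        zone=tuple(areas),
        sites=tuple(areas),
        site_centroid_mean_dist=mean_site_centroid_distance(areas),
    )


def select_top_density_cells(
    breed_pts: np.ndarray,
    grid_rect: Rect,
    nx: int = 15,
    ny: int = 15,
    k: int = 20,
) -> tuple[Rect, ...]:
    """The k highest-occupancy cells of a coarse grid over the breeding range.

    Each returned site is the grid cell itself.  Ties are broken by
    row-major cell index so the pool is deterministic.
    """
    breed_pts = np.asarray(breed_pts, dtype=float).reshape(-1, 2)
    if nx < 1 or ny < 1:
        raise ValueError("grid must have at least one cell per axis")
    ix = np.clip(
        ((breed_pts[:, 0] - grid_rect.xmin) / grid_rect.width * nx).astype(int), 0, nx - 1
    )
    iy = np.clip(
        ((breed_pts[:, 1] - grid_rect.ymin) / grid_rect.height * ny).astype(int), 0, ny - 1
    )
    counts = np.bincount(iy * nx + ix, minlength=nx * ny)
    occupied = int((counts > 0).sum())
    if occupied < k:
        raise ValueError(f"only {occupied} occupied cells; cannot select {k}")
    # stable sort on (-count, row-major index) -> deterministic tie-break
    order = np.lexsort((np.arange(nx * ny), -counts))[:k]
    w = grid_rect.width / nx
    h = grid_rect.height / ny
    sites = []
    for cell in order:
        cy, cx = divmod(int(cell), nx)
        sites.append(
            Rect(
                grid_rect.xmin + cx * w,
                grid_rect.ymin + cy * h,
                grid_rect.xmin + (cx + 1) * w,
                grid_rect.ymin + (cy + 1) * h,
            )
        )
    return tuple(sites)


def sample_sites(
    pop: PairedPopulation, design: SiteDesign, max_retries: int = 10
) -> SampleResult:
    """Draw k sites from the pool, then individuals from their union.

    If the union of an unlucky site selection holds fewer than ``n_sample``
    individuals the site draw is retried with a fresh sub-seed, a bounded
    number of times, before giving up.
    """
    last_err: InsufficientIndividualsError | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng((design.seed, attempt))
        site_idx = rng.choice(len(design.pool), size=design.k, replace=False)
        sites = tuple(design.pool[i] for i in site_idx)
        mask = union_contains(sites, pop.breed_xy)
        try:
            ids = _draw_from_mask(pop, mask, design.n_sample, rng)
        except InsufficientIndividualsError as err:
            last_err = err
            continue
        return SampleResult(
            design="sites",
            ids=ids,
            zone=bounding_rect(sites),
            sites=sites,
            site_centroid_mean_dist=(
                mean_site_centroid_distance(sites) if len(sites) >= 2 else None
            ),
        )
    raise InsufficientIndividualsError(
        last_err.available if last_err else 0, design.n_sample
    )


def mean_site_centroid_distance(sites) -> float:
    """Mean centroid-to-centroid distance over all unordered site pairs."""
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a centroid distance")
    cents = np.array([s.centroid for s in sites])
    d = [
        float(np.hypot(*(cents[i] - cents[j])))
        for i, j in combinations(range(len(sites)), 2)
    ]
    return float(np.mean(d))


def default_area_designs(
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    sides: tuple[float, ...] = DEFAULT_AREA_SIDES,
    n_sample: int = DEFAULT_N_SAMPLE,
) -> dict[str, AreaDesign]:
    """Small / medium / large centred sampling areas."""
    cx, cy = breeding_rect.centroid
    names = ("small", "medium", "large")[: len(sides)]
    return {
        name: AreaDesign(Rect.centred_square(cx, cy, side), n_sample)
        for name, side in zip(names, sides)
    }


def default_spread_designs(
    breeding_rect: Rect = DEFAULT_BREEDING_RECT,
    spacings: tuple[float, ...] = DEFAULT_SPREAD_SPACINGS,
    site_side: float = DEFAULT_SPREAD_SITE_SIDE,
    n_sample: int = DEFAULT_N_SAMPLE,
) -> dict[str, SpreadDesign]:
    """Low / medium / high spread grids with constant total sampled area."""
    names = ("low", "medium", "high")[: len(spacings)]
    return {
        name: SpreadDesign.centred_grid(spacing, site_side, breeding_rect, n_sample)
        for name, spacing in zip(names, spacings)
    }
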