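"""Realistic populations over arbitrary range polygons.

Real species are not uniformly spread over rectangles: their ranges have
irregular outlines and spatially clustered abundance.  This module emulates
that in three steps:

1. a stationary Gaussian random field (GRF) with squared-exponential
   covariance is simulated on a grid over the range's bounding box and
   min-max scaled to [0, 1], giving a per-cell occurrence weight surface;
2. individuals are distributed across the range with cell choice
   proportional to weight and position uniform within the cell's
   intersection with the range polygon;
3. breeding and non-breeding point sets are linked into one migratory
   population by *longitudinal-rank matching*: each point set is ranked by
   longitude (x), and a breeding point of rank r is paired, without
   replacement, with a uniformly chosen still-unassigned non-breeding point
   whose rank lies within +/- bandwidth of r.  A small bandwidth forces
   west-to-west / east-to-east pairings (strong connectivity); a bandwidth
   of the population size gives a uniformly random bijection (none).

Three synthetic range fixtures are bundled as GeoJSON — a wide, a compact
and an elongated range pair — standing in for diverse real-world range
geometries.  They are invented shapes, not replicas of any species' range.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .geometry import Rect
from .population import PairedPopulation

__all__ = [
    "RangePolygon",
    "GaussianFieldParams",
    "DensitySurface",
    "RankMatchParams",
    "generate_gaussian_field",
    "density_surface_for_range",
    "distribute_individuals",
    "match_by_longitudinal_rank",
    "build_realistic_population",
    "load_fixture",
    "FIXTURE_NAMES",
    "lag_correlation",
]

FIXTURE_NAMES = ("wide", "compact", "elongated")

#: bandwidths producing high / medium / low connectivity at n = 50,000
DEFAULT_BANDWIDTHS = {"high": 1000, "medium": 13000, "low": 25000}


@dataclass(frozen=True)
class RangePolygon:
    """A seasonal range: one (multi)polygon plus a coordinate-system flag."""

    season: Literal["breeding", "nonbreeding"]
    geometry: BaseGeometry
    crs_flag: Literal["planar", "geographic"] = "planar"

    def __post_init__(self) -> None:
        if self.season not in ("breeding", "nonbreeding"):
            raise ValueError("season must be 'breeding' or 'nonbreeding'")
        if not self.geometry.is_valid:
            raise ValueError("range polygon is invalid (self-intersecting?)")
        if self.geometry.area <= 0:
            raise ValueError("range polygon has zero area")

    @property
    def bbox(self) -> Rect:
        x0, y0, x1, y1 = self.geometry.bounds
        return Rect(x0, y0, x1, y1)


@dataclass(frozen=True)
class GaussianFieldParams:
    """Parameters of the latent Gaussian random field.

    ``autocorr_range`` is the correlation length in *cells* of the
    squared-exponential covariance; ``magnitude`` is the latent variance.
    Because the field is min-max scaled afterwards, magnitude mostly matters
    in the degenerate limit (zero magnitude gives a constant field).
    """

    grid_nx: int = 100
    grid_ny: int = 100
    autocorr_range: float = 10.0
    magnitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx * self.grid_ny < 2:
            raise ValueError("grid must have at least 2 cells")
        if self.autocorr_range <= 0:
            raise ValueError("autocorr_range must be > 0")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


class DensitySurface:
    """Grid of per-cell occurrence weights in [0, 1] over a bounding box."""

    def __init__(self, weights: np.ndarray, origin: tuple[float, float], cell_size: tuple[float, float]):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2:
            raise ValueError("weights must be a 2-D grid")
        if np.any(weights < 0) or np.any(weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = weights
        self.x0, self.y0 = origin
        self.dx, self.dy = cell_size

    @property
    def ny(self) -> int:
        return self.weights.shape[0]

    @property
    def nx(self) -> int:
        return self.weights.shape[1]

    def cell_rect(self, iy: int, ix: int) -> Rect:
        return Rect(
            self.x0 + ix * self.dx,
            self.y0 + iy * self.dy,
            self.x0 + (ix + 1) * self.dx,
            self.y0 + (iy + 1) * self.dy,
        )

    def to_ascii(self, path) -> None:
        """Write the grid as an ESRI ASCII raster (row order top-down)."""
        header = (
            f"NCOLS {self.nx}\nNROWS {self.ny}\n"
            f"XLLCORNER {self.x0:.17g}\nYLLCORNER {self.y0:.17g}\n"
            f"CELLSIZE {self.dx:.17g}\nNODATA_VALUE -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.weights[::-1], fmt="%.8g")


def _simulate_grf(ny: int, nx: int, corr_range: float, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary GRF via circulant embedding on a doubled torus."""
    M, N = 2 * ny, 2 * nx
    iy = np.minimum(np.arange(M), M - np.arange(M))
    ix = np.minimum(np.arange(N), N - np.arange(N))
    h2 = (iy[:, None] ** 2 + ix[None, :] ** 2) / corr_range**2
    cov = magnitude * np.exp(-0.5 * h2)
    eig = np.fft.fft2(cov).real
    eig = np.clip(eig, 0.0, None)  # embedding may be slightly indefinite
    xi = rng.normal(size=(M, N)) + 1j * rng.normal(size=(M, N))
    field = np.fft.ifft2(np.sqrt(eig) * xi).real * np.sqrt(M * N)
    return field[:ny, :nx]


def generate_gaussian_field(params: GaussianFieldParams, bbox: Rect | None = None) -> DensitySurface:
    """Simulate the latent field and min-max scale it to [0, 1].

    ``bbox`` fixes the surface's spatial footprint (defaults to a unit-cell
    grid at the origin).  A constant latent field — e.g. in the zero
    magnitude limit — has no min-max scaling; every weight is set to 0.5,
    which is equivalent to any other constant for proportional sampling.
    """
    rng = np.random.default_rng(params.seed)
    if params.magnitude == 0.0:
        latent = np.zeros((params.grid_ny, params.grid_nx))
    else:
        latent = _simulate_grf(
            params.grid_ny, params.grid_nx, params.autocorr_range, params.magnitude, rng
        )
    lo, hi = latent.min(), latent.max()
    if hi > lo:
        weights = (latent - lo) / (hi - lo)
    else:
        weights = np.full_like(latent, 0.5)
    if bbox is None:
        bbox = Rect(0.0, 0.0, float(params.grid_nx), float(params.grid_ny))
    cell = (bbox.width / params.grid_nx, bbox.height / params.grid_ny)
    return DensitySurface(weights, (bbox.xmin, bbox.ymin), cell)


def density_surface_for_range(polygon: RangePolygon, params: GaussianFieldParams) -> DensitySurface:
    """GRF surface over the polygon's bounding box, zeroed outside the range.

    A cell keeps its weight only if its intersection with the range polygon
    covers at least 0.1% of the cell, so every positive-weight cell can
    host points by rejection sampling; boundary slivers below that are
    treated as outside (a negligible trim at the default 100 x 100
    resolution).
    """
    surface = generate_gaussian_field(params, bbox=polygon.bbox)
    xs = surface.x0 + np.arange(surface.nx) * surface.dx
    ys = surface.y0 + np.arange(surface.ny) * surface.dy
    boxes = shapely.box(
        *np.broadcast_arrays(
            xs[None, :], ys[:, None], xs[None, :] + surface.dx, ys[:, None] + surface.dy
        )
    )
    inter = shapely.area(shapely.intersection(boxes, polygon.geometry))
    surface.weights = surface.weights * (inter > 1e-3 * surface.dx * surface.dy)
    return surface


def distribute_individuals(
    surface: DensitySurface, polygon: RangePolygon, n: int, seed: int = 0
) -> np.ndarray:
    """Place ``n`` points: cells chosen proportionally to weight, positions
    uniform within each chosen cell's intersection with the polygon."""
    if n < 0:
        raise ValueError("n must be >= 0")
    w = surface.weights.ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("all surface weights are zero; nothing to sample from")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, w / total)
    pts = np.empty((n, 2))
    filled = 0
    for cell in np.nonzero(counts)[0]:
        need = int(counts[cell])
        iy, ix = divmod(int(cell), surface.nx)
        rect = surface.cell_rect(iy, ix)
        got = 0
        for _ in range(10_000):  # rejection sampling within the cell
            batch = max(4 * (need - got), 16)
            cand = np.column_stack(
                [
                    rng.uniform(rect.xmin, rect.xmax, batch),
                    rng.uniform(rect.ymin, rect.ymax, batch),
                ]
            )
            ok = shapely.contains_xy(polygon.geometry, cand[:, 0], cand[:, 1])
            take = cand[ok][: need - got]
            pts[filled + got : filled + got + len(take)] = take
            got += len(take)
            if got == need:
                break
        else:
            raise RuntimeError(
                f"could not place points in cell {cell}: intersection with the "
                "range polygon appears to have negligible area"
            )
        filled += need
    return pts


@dataclass(frozen=True)
class RankMatchParams:
    """Bandwidth (in longitudinal ranks) and seed of the matching step."""

    bandwidth: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")


class _Fenwick:
    """Binary indexed tree over availability flags, 1-based ranks."""

    def __init__(self, n: int):
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)
        for i in range(1, n + 1):  # build with all ranks available
            self.tree[i] += 1
            j = i + (i & -i)
            if j <= n:
                self.tree[j] += self.tree[i]

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & -i
        return int(s)

    def remove(self, i: int) -> None:
        while i <= self.n:
            self.tree[i] -= 1
            i += i & -i

    def find_kth(self, k: int) -> int:
        """Smallest rank whose availability prefix sum equals k."""
        pos = 0
        bit = 1 << (self.n.bit_length())
        while bit:
            nxt = pos + bit
            if nxt <= self.n and self.tree[nxt] < k:
                pos = nxt
                k -= self.tree[nxt]
            bit >>= 1
        return pos + 1


def _longitude_ranks(points: np.ndarray) -> np.ndarray:
    """Positions sorted by longitude; ties broken by latitude then index.

    Returns ``order`` such that ``points[order[r]]`` is the point of rank
    r+1 (0-based r).
    """
    idx = np.arange(len(points))
    return np.lexsort((idx, points[:, 1], points[:, 0]))


def match_by_longitudinal_rank(
    breed_pts: np.ndarray,
    nonbreed_pts: np.ndarray,
    params: RankMatchParams,
) -> PairedPopulation:
    """Pair seasons by longitudinal rank within a +/- bandwidth window.

    Breeding individuals are processed in random order; each draws
    uniformly among the still-unassigned non-breeding points whose
    longitude rank lies in ``[rank - b, rank + b]`` (clamped at the range
    edges).  When the sequential draw strands an individual whose window
    is fully consumed, the partial assignment is repaired with an
    augmenting path that stays inside everyone's window (the identity
    pairing is always feasible, so such a path always exists); see
    ``docs/methods.md`` for why this beats restarting.
    """
    breed_pts = np.asarray(breed_pts, dtype=float).reshape(-1, 2)
    nonbreed_pts = np.asarray(nonbreed_pts, dtype=float).reshape(-1, 2)
    n = len(breed_pts)
    if len(nonbreed_pts) != n:
        raise ValueError("breeding and non-breeding point sets differ in size")
    if n == 0:
        return PairedPopulation(breed_pts, nonbreed_pts.copy())
    b = params.bandwidth

    breed_order = _longitude_ranks(breed_pts)  # breed_order[r] = point index of rank r+1
    nonbreed_order = _longitude_ranks(nonbreed_pts)
    breed_rank = np.empty(n, dtype=np.int64)
    breed_rank[breed_order] = np.arange(1, n + 1)

    rng = np.random.default_rng(params.seed)
    tree = _Fenwick(n)
    owner = np.full(n + 1, -1, dtype=np.int64)  # nonbreed rank -> breeding index

    def window(i: int) -> tuple[int, int]:
        r = int(breed_rank[i])
        return max(1, r - b), min(n, r + b)

    def assign(i: int, visited: set[int]) -> bool:
        """Kuhn-style augmentation: give i an available rank in its window,
        or displace a current owner who can move elsewhere."""
        lo, hi = window(i)
        below = tree.prefix(lo - 1)
        avail = tree.prefix(hi) - below
        if avail > 0:
            pick = tree.find_kth(below + int(rng.integers(1, avail + 1)))
            tree.remove(pick)
            owner[pick] = i
            return True
        for q in lo + rng.permutation(hi - lo + 1):
            if q in visited:
                continue
            visited.add(int(q))
            if assign(int(owner[q]), visited):
                owner[q] = i
                return True
        return False

    limit = sys.getrecursionlimit()
    if limit < n + 1000:
        sys.setrecursionlimit(n + 1000)
    try:
        for i in rng.permutation(n):
            if not assign(int(i), set()):
                raise RuntimeError(
                    f"rank matching infeasible (bandwidth {b}, n {n})"
                )
    finally:
        sys.setrecursionlimit(limit)

    partner = np.empty(n, dtype=np.int64)
    ranks = np.nonzero(owner[1:] >= 0)[0] + 1
    partner[owner[ranks]] = nonbreed_order[ranks - 1]
    return PairedPopulation(breed_pts, nonbreed_pts[partner])


def build_realistic_population(
    breed_range: RangePolygon,
    nonbreed_range: RangePolygon,
    field_params: GaussianFieldParams,
    n: int,
    rank_params: RankMatchParams,
) -> PairedPopulation:
    """GRF density -> point placement -> rank matching, for both seasons.

    Each season gets its own independent density surface; the four random
    stages draw reproducible sub-seeds from ``field_params.seed``.
    """
    ss = np.random.SeedSequence(field_params.seed)
    s_field_b, s_field_w, s_pts_b, s_pts_w = [
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    ]
    surf_b = density_surface_for_range(
        breed_range,
        GaussianFieldParams(
            field_params.grid_nx, field_params.grid_ny,
            field_params.autocorr_range, field_params.magnitude, s_field_b,
        ),
    )
    surf_w = density_surface_for_range(
        nonbreed_range,
        GaussianFieldParams(
            field_params.grid_nx, field_params.grid_ny,
            field_params.autocorr_range, field_params.magnitude, s_field_w,
        ),
    )
    breed_pts = distribute_individuals(surf_b, breed_range, n, s_pts_b)
    nonbreed_pts = distribute_individuals(surf_w, nonbreed_range, n, s_pts_w)
    return match_by_longitudinal_rank(breed_pts, nonbreed_pts, params=rank_params)


def load_fixture(name: str) -> tuple[RangePolygon, RangePolygon]:
    """Load a bundled synthetic range pair: (breeding, nonbreeding)."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = resources.files("migconn.data").joinpath(f"{name}.geojson").read_text()
    return ranges_from_geojson(text)


def ranges_from_geojson(text_or_dict) -> tuple[RangePolygon, RangePolygon]:
    """Parse a GeoJSON FeatureCollection with 'season'-tagged features."""
    gj = json.loads(text_or_dict) if isinstance(text_or_dict, str) else text_or_dict
    found: dict[str, RangePolygon] = {}
    for feat in gj["features"]:
        season = feat["properties"]["season"]
        crs_flag = feat["properties"].get("crs_flag", "planar")
        found[season] = RangePolygon(season, shapely_shape(feat["geometry"]), crs_flag)
    if set(found) != {"breeding", "nonbreeding"}:
        raise ValueError("GeoJSON must contain one breeding and one nonbreeding feature")
    return found["breeding"], found["nonbreeding"]


def lag_correlation(field: np.ndarray, lag: int) -> float:
    """Empirical spatial autocorrelation at an axis-aligned lag (correlogram
    point): mean of the horizontal- and vertical-shift Pearson correlations."""
    f = np.asarray(field, dtype=float)
    cx = np.corrcoef(f[:, :-lag].ravel(), f[:, lag:].ravel())[0, 1]
    cy = np.corrcoef(f[:-lag, :].ravel(), f[lag:, :].ravel())[0, 1]
    return float((cx + cy) / 2.0)
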