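"""Sampling designs: footprints, uniformity, site pools, centroid distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migconn import (
    AreaDesign,
    InsufficientIndividualsError,
    PairedPopulation,
    Rect,
    SiteDesign,
    SpreadDesign,
    default_spread_designs,
    mean_site_centroid_distance,
    sample_area,
    sample_patchy,
    sample_sites,
    sample_spread_grid,
    select_top_density_cells,
)
from migconn.geometry import bounding_rect, union_contains


class TestAreaSampling:
    def test_sample_is_unique_and_in_bounds(self, small_population):
        design = AreaDesign(Rect(200, 200, 800, 800), n_sample=50)
        res = sample_area(small_population, design, seed=1)
        assert len(res.ids) == 50
        assert len(set(res.ids.tolist())) == 50
        sub = small_population.select_ids(res.ids)
        assert design.area.contains(sub.breed_xy).all()

    def test_whole_range_full_sample_is_identity(self, small_population):
        design = AreaDesign(Rect(-1, -1, 1001, 1001), n_sample=small_population.n)
        res = sample_area(small_population, design, seed=2)
        assert set(res.ids.tolist()) == set(small_population.ids.tolist())

    def test_insufficient_individuals_error_names_shortfall(self, small_population):
        design = AreaDesign(Rect(0, 0, 20, 20), n_sample=400)
        with pytest.raises(InsufficientIndividualsError, match="400"):
            sample_area(small_population, design, seed=3)

    def test_inclusion_probability_uniform(self):
        # 2,000 draws of 10 from 100: per-individual frequency ~ Binomial(2000, 0.1)
        pop = PairedPopulation(
            np.random.default_rng(5).uniform(0, 1, (100, 2)),
            np.zeros((100, 2)),
        )
        design = AreaDesign(Rect(0, 0, 1, 1), n_sample=10)
        counts = np.zeros(100)
        for rep in range(2000):
            res = sample_area(pop, design, seed=rep)
            counts[res.ids] += 1
        freq = counts / 2000
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert (np.abs(freq - 0.1) < 4 * se).all()

    def test_reproducible_under_seed(self, small_population):
        design = AreaDesign(Rect(100, 100, 900, 900), n_sample=30)
        a = sample_area(small_population, design, seed=9)
        b = sample_area(small_population, design, seed=9)
        np.testing.assert_array_equal(a.ids, b.ids)


class TestSpreadSampling:
    def test_pooled_draw_from_nine_sites(self, small_population):
        design = SpreadDesign.centred_grid(
            spacing=250.0, site_side=100.0, breeding_rect=Rect(0, 0, 1000, 1000),
            n_sample=40,
        )
        res = sample_spread_grid(small_population, design, seed=4)
        sub = small_population.select_ids(res.ids)
        assert union_contains(design.sites, sub.breed_xy).all()
        assert res.zone == bounding_rect(design.sites)

    def test_breeding_distances_bounded_by_zone_diameter(self, small_population):
        design = SpreadDesign.centred_grid(
            spacing=300.0, site_side=150.0, breeding_rect=Rect(0, 0, 1000, 1000),
            n_sample=30,
        )
        res = sample_spread_grid(small_population, design, seed=5)
        sub = small_population.select_ids(res.ids)
        from scipy.spatial.distance import pdist

        assert pdist(sub.breed_xy).max() <= res.zone.diameter + 1e-9

    def test_high_spread_rightshifts_breeding_distances(self, small_population):
        """Scattered sites oversample large breeding pairwise distances
        relative to all individuals in the zone."""
        from scipy.spatial.distance import pdist

        design = SpreadDesign.centred_grid(
            spacing=400.0, site_side=150.0, breeding_rect=Rect(0, 0, 1000, 1000),
            n_sample=40,
        )
        means_sampled = []
        for rep in range(20):
            res = sample_spread_grid(small_population, design, seed=rep)
            sub = small_population.select_ids(res.ids)
            means_sampled.append(pdist(sub.breed_xy).mean())
        zone = bounding_rect(design.sites)
        in_zone = small_population.subset(zone.contains(small_population.breed_xy))
        assert np.mean(means_sampled) > pdist(in_zone.breed_xy).mean()

    def test_default_designs_hold_total_area_constant(self):
        designs = default_spread_designs()
        areas = {sum(s.area for s in d.sites) for d in designs.values()}
        assert len(areas) == 1

    def test_overlapping_spacing_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SpreadDesign.centred_grid(spacing=50.0, site_side=100.0)


class TestPatchySampling:
    def test_allocation_tracks_in_area_counts(self, small_population):
        areas = (
            Rect(0, 0, 500, 500),
            Rect(500, 0, 1000, 500),
            Rect(0, 500, 500, 1000),
            Rect(500, 500, 1000, 1000),
        )
        in_counts = np.array(
            [a.contains(small_population.breed_xy).sum() for a in areas], dtype=float
        )
        expected = 100 * in_counts / in_counts.sum()
        got = np.zeros(4)
        for rep in range(200):
            res = sample_patchy(small_population, areas, n_sample=100, seed=rep)
            sub = small_population.select_ids(res.ids)
            for i, a in enumerate(areas):
                got[i] += a.contains(sub.breed_xy).sum()
        got /= 200
        # multinomial SE per area over 200 pooled draws
        p = in_counts / in_counts.sum()
        se = np.sqrt(100 * p * (1 - p) / 200)
        assert (np.abs(got - expected) < 4 * se).all()

    def test_wrong_area_count_rejected(self, small_population):
        with pytest.raises(ValueError):
            sample_patchy(small_population, (Rect(0, 0, 1, 1),) * 3, 10, 0)


class TestSitePool:
    def test_counts_match_bruteforce_per_cell(self, rng):
        pts = rng.uniform(0, 30, size=(500, 2))
        grid = Rect(0, 0, 30, 30)
        sites = select_top_density_cells(pts, grid, nx=3, ny=3, k=4)
        # brute-force count per 10x10 cell
        counts = {}
        for cy in range(3):
            for cx in range(3):
                cell = Rect(10 * cx, 10 * cy, 10 * (cx + 1), 10 * (cy + 1))
                inside = (
                    (pts[:, 0] >= cell.xmin) & (pts[:, 0] < cell.xmax if cx < 2 else pts[:, 0] <= cell.xmax)
                    & (pts[:, 1] >= cell.ymin) & (pts[:, 1] < cell.ymax if cy < 2 else pts[:, 1] <= cell.ymax)
                )
                counts[(cx, cy)] = int(inside.sum())
        top4 = sorted(counts.values(), reverse=True)[:4]
        got = []
        for s in sites:
            cx, cy = int(s.xmin // 10), int(s.ymin // 10)
            got.append(counts[(cx, cy)])
        assert sorted(got, reverse=True) == top4

    def test_single_cell_case(self):
        pts = np.full((50, 2), 5.0)
        sites = select_top_density_cells(pts, Rect(0, 0, 10, 10), nx=2, ny=2, k=1)
        assert len(sites) == 1
        assert sites[0].contains(np.array([[5.0, 5.0]]))[0]

    def test_too_few_occupied_cells(self):
        pts = np.full((50, 2), 5.0)
        with pytest.raises(ValueError, match="occupied"):
            select_top_density_cells(pts, Rect(0, 0, 10, 10), nx=2, ny=2, k=3)


class TestSiteSampling:
    def _pool(self):
        rng = np.random.default_rng(3)
        pop = PairedPopulation(
            rng.uniform(0, 100, (4000, 2)), rng.uniform(0, 100, (4000, 2))
        )
        pool = select_top_density_cells(pop.breed_xy, Rect(0, 0, 100, 100),
                                        nx=5, ny=5, k=20)
        return pop, pool

    def test_k_sites_selected_and_sample_in_union(self):
        pop, pool = self._pool()
        design = SiteDesign(pool, k=5, n_sample=100, seed=7)
        res = sample_sites(pop, design)
        assert len(res.sites) == 5
        sub = pop.select_ids(res.ids)
        assert union_contains(res.sites, sub.breed_xy).all()
        assert res.site_centroid_mean_dist > 0

    def test_k3_more_variable_than_k20(self):
        """Fewer discrete sites -> larger spread of the zone covered,
        hence more variable samples of breeding locations."""
        pop, pool = self._pool()
        spans = {k: [] for k in (3, 20)}
        for k in (3, 20):
            for rep in range(30):
                res = sample_sites(pop, SiteDesign(pool, k=k, n_sample=100, seed=rep))
                sub = pop.select_ids(res.ids)
                spans[k].append(sub.breed_xy[:, 0].std())
        assert np.var(spans[3]) > np.var(spans[20])

    def test_invalid_pool_or_k(self):
        _, pool = self._pool()
        with pytest.raises(ValueError):
            SiteDesign(pool[:10], k=3)
        with pytest.raises(ValueError):
            SiteDesign(pool, k=2)
        with pytest.raises(ValueError):
            SiteDesign(pool, k=21)


class TestCentroidDistance:
    def test_two_sites(self):
        a, b = Rect(0, 0, 2, 2), Rect(10, 0, 12, 2)
        assert mean_site_centroid_distance([a, b]) == pytest.approx(10.0)

    def test_3_4_5_layout(self):
        # centroids (0,0), (3,0), (0,4): pair distances 3, 4, 5 -> mean 4
        sites = [
            Rect.centred_square(0, 0, 1),
            Rect.centred_square(3, 0, 1),
            Rect.centred_square(0, 4, 1),
        ]
        assert mean_site_centroid_distance(sites) == pytest.approx(4.0)

    def test_single_site_undefined(self):
        with pytest.raises(ValueError):
            mean_site_centroid_distance([Rect(0, 0, 1, 1)])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=6, unique=True))
    def test_matches_pair_enumeration(self, centres):
        sites = [Rect.centred_square(x, y, 1.0) for x, y in centres]
        got = mean_site_centroid_distance(sites)
        ds = []
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                ds.append(np.hypot(centres[i][0] - centres[j][0],
                                   centres[i][1] - centres[j][1]))
        assert got == pytest.approx(float(np.mean(ds)))
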