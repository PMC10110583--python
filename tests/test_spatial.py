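"""Spatial profiling: grids, boundaries, signed distances, bands, co-exclusion."""
import numpy as np
import pandas as pd
import pytest
import shapely.wkt
from shapely.geometry import Polygon

from vhlkit import simulate, spatial
from vhlkit.spatial import (
    RegionBoundary,
    RegionBoundaryEstimator,
    co_exclusion_profile,
    co_exclusion_permutation_null,
    density_grid,
    fit_exponential_decay,
    infer_region_boundary,
    infiltration_profile,
    positivity_fraction_by_region,
    signed_distance_to_boundary,
)


def cells_frame(xy, **markers):
    df = pd.DataFrame(xy, columns=["x_um", "y_um"])
    for name, values in markers.items():
        df[name] = values
    return df


def true_boundary(truth):
    return RegionBoundary.from_geometry(shapely.wkt.loads(truth["region_wkt"]))


class TestDensityGrid:
    def test_counts_conserved(self, rng):
        cells = cells_frame(rng.uniform(0, 3000, (500, 2)), M=True)
        grid = density_grid(cells, "M", cell_size=100, bandwidth=200)
        assert grid.counts.sum() == 500

    def test_point_mass_argmax(self):
        xy = np.tile([[1234.0, 2345.0]], (40, 1))
        grid = density_grid(cells_frame(xy, M=True), "M")
        gx, gy = grid.argmax_xy()
        assert abs(gx - 1234) <= grid.cell_size and abs(gy - 2345) <= grid.cell_size

    def test_uniform_field_is_flat_away_from_edges(self, rng):
        cells = cells_frame(rng.uniform(0, 6000, (4000, 2)), M=True)
        grid = density_grid(cells, "M", cell_size=100, bandwidth=600)
        interior = grid.density[15:-15, 15:-15]
        assert interior.max() / interior.min() < 2

    def test_two_clusters_equal_maxima(self, rng):
        a = rng.normal([1000, 1000], 150, (500, 2))
        b = rng.normal([5000, 5000], 150, (500, 2))
        grid = density_grid(cells_frame(np.vstack([a, b]), M=True),
                            "M", cell_size=100, bandwidth=200)
        half = len(grid.x_centers) // 2
        peak_a = grid.density[:half, :half].max()
        peak_b = grid.density[half:, half:].max()
        assert abs(peak_a - peak_b) / max(peak_a, peak_b) < 0.10

    def test_empty_positive_set_errors(self):
        cells = cells_frame([[0.0, 0.0]], M=False)
        with pytest.raises(ValueError):
            density_grid(cells, "M")


class TestBoundary:
    def test_disc_area_recovered(self, rng):
        r = 2000.0
        theta = rng.uniform(0, 2 * np.pi, 4000)
        rad = r * np.sqrt(rng.uniform(0, 1, 4000))
        xy = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
        noise = cells_frame(rng.uniform(-4000, 4000, (200, 2)), M=False)
        cells = pd.concat([cells_frame(xy, M=True), noise], ignore_index=True)
        boundary = infer_region_boundary(cells, "M", cell_size=100, bandwidth=200)
        assert boundary.area == pytest.approx(np.pi * r ** 2, rel=0.25)

    def test_two_discs_two_polygons(self, rng):
        a = rng.normal([0, 0], 400, (1500, 2))
        b = rng.normal([8000, 8000], 400, (1500, 2))
        cells = cells_frame(np.vstack([a, b]), M=True)
        boundary = infer_region_boundary(cells, "M", cell_size=200, bandwidth=300)
        assert boundary.n_polygons == 2

    def test_degenerate_threshold_errors(self):
        cells = cells_frame([[0.0, 0.0], [10.0, 10.0]], M=True)
        with pytest.raises(ValueError):
            infer_region_boundary(cells, "M", density_threshold=1.5)


class TestSignedDistance:
    square = RegionBoundary.from_geometry(
        Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)]))

    def test_vertex_is_zero(self):
        assert signed_distance_to_boundary([[0.0, 0.0]], self.square)[0] == 0.0

    def test_outside_unit_square_edge(self):
        # closed form: 250 µm beyond the x=1000 edge
        d = signed_distance_to_boundary([[1250.0, 500.0]], self.square)[0]
        assert d == pytest.approx(250.0)

    def test_centroid_of_disc_is_minus_radius(self):
        b = RegionBoundary.from_geometry(simulate.disc(0, 0, 800))
        d = signed_distance_to_boundary([[0.0, 0.0]], b)[0]
        assert d == pytest.approx(-800.0, rel=0.01)

    def test_continuous_across_boundary(self):
        eps = 1.0
        d = signed_distance_to_boundary(
            [[1000 - eps, 500.0], [1000 + eps, 500.0]], self.square)
        assert d[0] < 0 < d[1]
        assert abs(d[0] + d[1]) < 2 * eps


class TestInfiltration:
    def test_band_counts_conserved(self, infiltration_tissue):
        cells, truth = infiltration_tissue
        prof = infiltration_profile(cells, "Ki67", true_boundary(truth))
        n_pos = int(cells["Ki67"].sum())
        assert int(prof.counts.sum()) + prof.n_out_of_band == n_pos

    def test_uniform_poisson_within_3_sigma(self, rng):
        lam = 2e-4
        xy = rng.uniform(0, 8000, (int(lam * 8000 * 8000), 2))
        cells = cells_frame(xy, M=True)
        b = RegionBoundary.from_geometry(
            Polygon([(2000, 2000), (6000, 2000), (6000, 6000), (2000, 6000)]))
        # clip bands to the actual point window, not the expanded default
        from shapely.geometry import box
        prof = infiltration_profile(cells, "M", b, window=box(0, 0, 8000, 8000))
        for count, area in zip(prof.counts, prof.areas):
            if area > 0:
                expected = lam * area
                assert abs(count - expected) <= 3 * np.sqrt(expected) + 3

    def test_confined_phenotype_zero_outside(self, rng):
        b = RegionBoundary.from_geometry(simulate.disc(0, 0, 2000))
        spec = simulate.TissueSpec(
            window=(-5000, -5000, 5000, 5000),
            region=simulate.disc(0, 0, 2000),
            phenotypes=(simulate.PhenotypePattern(
                {"M": True}, simulate.uniform_inside(3e-4), 3e-4),),
        )
        cells, _ = simulate.simulate_tissue(spec, seed=4)
        prof = infiltration_profile(cells, "M", b)
        outside = [c for (lo, hi), c in zip(prof.bins, prof.counts) if lo >= 0]
        assert sum(outside) == 0

    def test_exponential_decay_recovers_tau(self, infiltration_tissue):
        cells, truth = infiltration_tissue
        prof = infiltration_profile(cells, "Ki67", true_boundary(truth))
        _, tau = fit_exponential_decay(prof)
        assert tau == pytest.approx(1000.0, rel=0.2)

    def test_rigid_motion_invariance(self, infiltration_tissue):
        cells, truth = infiltration_tissue
        boundary = true_boundary(truth)
        prof = infiltration_profile(cells, "Ki67", boundary)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        xy = cells[["x_um", "y_um"]].to_numpy() @ R.T + [12345.0, -6789.0]
        moved = cells.copy()
        moved[["x_um", "y_um"]] = xy
        from shapely import affinity
        geom = affinity.translate(
            affinity.rotate(boundary.polygons, theta, origin=(0, 0),
                            use_radians=True), 12345.0, -6789.0)
        prof2 = infiltration_profile(moved, "Ki67",
                                     RegionBoundary.from_geometry(geom))
        np.testing.assert_array_equal(prof.counts, prof2.counts)

    def test_doubling_cells_doubles_counts(self, infiltration_tissue):
        cells, truth = infiltration_tissue
        boundary = true_boundary(truth)
        prof = infiltration_profile(cells, "Ki67", boundary)
        doubled = pd.concat([cells, cells], ignore_index=True)
        prof2 = infiltration_profile(doubled, "Ki67", boundary)
        np.testing.assert_array_equal(prof2.counts, 2 * prof.counts)
        r1, r2 = prof.densities, prof2.densities
        ok = (r1 > 0)
        np.testing.assert_allclose(r2[ok] / r1[ok], 2.0, rtol=1e-9)


class TestPositivityFractions:
    def test_counting(self):
        xy = np.column_stack([np.linspace(100, 900, 40), np.full(40, 500.0)])
        target = [True] * 10 + [False] * 30
        cells = cells_frame(xy, T=target)
        region = RegionBoundary.from_geometry(
            Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)]))
        out = positivity_fraction_by_region(cells, "T", {"A": region})
        row = out.set_index("region").loc["A"]
        assert row["fraction"] == pytest.approx(0.25)

    def test_all_positive_and_outside_bucket(self):
        cells = cells_frame([[500.0, 500.0], [5000.0, 5000.0]], T=[True, True])
        region = RegionBoundary.from_geometry(
            Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)]))
        out = positivity_fraction_by_region(cells, "T", {"A": region}).set_index("region")
        assert out.loc["A", "fraction"] == 1.0
        assert out.loc["neither", "n_cells"] == 1

    def test_planted_fractions_within_binomial_bounds(self, rng):
        n = 2000
        xy_a = rng.uniform(0, 1000, (n, 2))
        xy_b = rng.uniform(2000, 3000, (n, 2))
        t = np.concatenate([rng.uniform(size=n) < 0.3, rng.uniform(size=n) < 0.05])
        cells = cells_frame(np.vstack([xy_a, xy_b]), T=t)
        regions = {
            "A": RegionBoundary.from_geometry(
                Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])),
            "B": RegionBoundary.from_geometry(
                Polygon([(2000, 2000), (3000, 2000), (3000, 3000), (2000, 3000)])),
        }
        out = positivity_fraction_by_region(cells, "T", regions).set_index("region")
        for label, p in (("A", 0.3), ("B", 0.05)):
            half_ci = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(out.loc[label, "fraction"] - p) <= half_ci


PHENO_A = {"VHL": True, "POSTN": False}
PHENO_B = {"VHL": False, "POSTN": True}


class TestCoExclusion:
    def test_monotone_opposite_curves_give_minus_one(self):
        cells, truth = simulate.simulate_tissue(
            simulate.default_coexclusion_tissue(seed=5))
        res = co_exclusion_profile(cells, PHENO_A, PHENO_B, true_boundary(truth))
        assert res.spearman <= -0.9

    def test_hard_exclusion_tie_limited_value(self):
        # step-function exclusion leaves exact-zero bands tied; with 4 inside
        # and 8 outside bands the midrank Spearman is -0.813 deterministically
        cells, truth = simulate.simulate_tissue(
            simulate.default_coexclusion_tissue(seed=5, hard=True))
        res = co_exclusion_profile(cells, PHENO_A, PHENO_B, true_boundary(truth))
        assert res.spearman == pytest.approx(-0.813, abs=0.02)

    def test_uniform_tissue_within_permutation_null(self):
        cells, truth = simulate.simulate_tissue(simulate.uniform_tissue(seed=0))
        obs, null = co_exclusion_permutation_null(
            cells, PHENO_A, PHENO_B, true_boundary(truth),
            n_permutations=199, seed=0)
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / (1 + len(null))
        assert p > 0.05

    def test_too_few_bands_undefined(self):
        cells, truth = simulate.simulate_tissue(
            simulate.default_coexclusion_tissue(seed=5))
        res = co_exclusion_profile(cells, PHENO_A, PHENO_B, true_boundary(truth),
                                   inner_extent=500, outer_extent=500,
                                   band_width=500)
        assert res.n_bands_used < 3 or not np.isnan(res.spearman)


class TestEstimator:
    def test_fit_transform_signs(self, infiltration_tissue):
        cells, truth = infiltration_tissue
        est = RegionBoundaryEstimator(marker="VHL", cell_size=200,
                                      bandwidth=400).fit(cells)
        d = est.transform(cells)
        vhl = cells["VHL"].to_numpy()
        # VHL-positive cells should mostly fall inside their own region
        assert (d[vhl] < 0).mean() > 0.8

    def test_unfitted_transform_errors(self, infiltration_tissue):
        cells, _ = infiltration_tissue
        with pytest.raises(RuntimeError):
            RegionBoundaryEstimator().transform(cells)
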