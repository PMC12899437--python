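"""Landscape analysis: minima, basins, barriers, extents, convergence."""

import itertools

import numpy as np
import pytest

from gagfes.fes import FreeEnergySurface, PeriodicGrid2D, normalize_min_zero
from gagfes.landscape import (BasinDecomposition, barrier_height,
                              basin_extent, compare_replicates,
                              crop_phi_report, find_local_minima, min_shift,
                              minimax_saddle, quadrant, segment_basins)
from gagfes.toy import ToyPotential, potential_grid


from conftest import brute_force_minimax, enumerate_paths_minimax, surface


class TestLocalMinima:
    def test_single_well(self):
        p = ToyPotential(wells=((10.0, -20.0, 5.0, 6.0),))
        minima = find_local_minima(potential_grid(p, nbins=72), ceiling=4.0)
        assert len(minima) == 1
        assert (minima[0].phi, minima[0].psi) == (10.0, -20.0)

    def test_constant_surface_empty(self):
        assert find_local_minima(surface(np.zeros((12, 12)))) == []

    def test_plateau_collapses_to_smallest_index(self):
        v = np.full((8, 8), 5.0)
        v[2:4, 3:5] = 1.0  # flat 2x2 plateau
        minima = find_local_minima(surface(v - 1.0), ceiling=10.0)
        assert len(minima) == 1
        assert (minima[0].i, minima[0].j) == (2, 3)

    def test_sorted_by_depth(self):
        v = np.full((16, 16), 8.0)
        v[2, 2] = 1.0
        v[10, 10] = 0.0
        minima = find_local_minima(surface(v), ceiling=10.0)
        assert [(m.i, m.j) for m in minima] == [(10, 10), (2, 2)]


class TestSegmentation:
    def test_two_symmetric_wells_equal_areas(self):
        p = ToyPotential(wells=((-90.0, 0.0, 5.0, 4.0), (90.0, 0.0, 5.0, 4.0)))
        fes = potential_grid(p, nbins=72)
        minima = find_local_minima(fes, ceiling=4.0)
        dec = segment_basins(fes, minima, ceiling=1e9)
        areas = [(dec.labels == k).sum() for k in range(len(minima))]
        # equal up to the two seam columns, whose bins are exactly
        # equidistant and go to one side by the deterministic tie-break
        assert abs(areas[0] - areas[1]) <= 2 * 72
        assert min(areas) > 0.4 * sum(areas)

    def test_bins_above_ceiling_unlabelled(self):
        p = ToyPotential(wells=((0.0, 0.0, 6.0, 8.0),))
        fes = potential_grid(p, nbins=36)
        minima = find_local_minima(fes, ceiling=3.0)
        dec = segment_basins(fes, minima, ceiling=3.0)
        assert np.all(dec.labels[fes.grid.values >= 3.0] == -1)
        assert np.all(dec.labels[fes.grid.values < 3.0] >= 0)

    def test_matches_descent_oracle_on_small_grid(self, rng):
        """Label assignment equals explicit steepest-descent path-following
        on a random 12x12 torus."""
        v = rng.standard_normal((12, 12))
        fes = surface(v)
        minima = find_local_minima(fes, ceiling=np.inf)
        dec = segment_basins(fes, minima, ceiling=np.inf)
        neigh = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
        vv = fes.grid.values
        pos = {(m.i, m.j): k for k, m in enumerate(minima)}
        for i in range(12):
            for j in range(12):
                ci, cj = i, j
                for _ in range(200):
                    if (ci, cj) in pos:
                        break
                    cand = [(vv[(ci + di) % 12, (cj + dj) % 12],
                             (ci + di) % 12, (cj + dj) % 12)
                            for di, dj in neigh]
                    best = min(cand)
                    if best[0] >= vv[ci, cj]:
                        break
                    ci, cj = best[1], best[2]
                assert dec.labels[i, j] == pos.get((ci, cj), dec.labels[i, j])


class TestBarriers:
    def test_same_basin_zero(self, two_basin_truth):
        minima = find_local_minima(two_basin_truth, ceiling=5.0)
        dec = segment_basins(two_basin_truth, minima)
        assert barrier_height(dec, two_basin_truth, 0, 0) == 0.0

    def test_designed_barrier_recovered(self, two_basin_truth):
        minima = find_local_minima(two_basin_truth, ceiling=5.0)
        dec = segment_basins(two_basin_truth, minima)
        sec = next(k for k, m in enumerate(minima)
                   if (m.phi, m.psi) == (-97.5, -80.0))
        glob = 1 - sec
        assert barrier_height(dec, two_basin_truth, sec, glob) == \
            pytest.approx(4.0, abs=0.1)

    @pytest.mark.parametrize("nx,ny", [(3, 3), (4, 5), (5, 6), (6, 6), (7, 7)])
    def test_widest_path_equals_threshold_scan(self, nx, ny, rng):
        for _ in range(5):
            v = rng.uniform(0, 10, (nx, ny))
            fes = surface(v)
            start = (0, 0)
            end = (nx // 2, ny - 1)
            got = minimax_saddle(fes, start, end)
            want = brute_force_minimax(fes.grid.values, start, end)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("nx,ny", [(3, 3), (3, 4)])
    def test_widest_path_equals_literal_path_enumeration(self, nx, ny, rng):
        for _ in range(3):
            v = rng.uniform(0, 10, (nx, ny))
            fes = surface(v)
            got = minimax_saddle(fes, (0, 0), (nx - 1, ny - 1))
            want = enumerate_paths_minimax(fes.grid.values, (0, 0),
                                           (nx - 1, ny - 1))
            assert got == pytest.approx(want, abs=1e-12)

    def test_saddle_symmetric_escape_asymmetric(self, two_basin_truth):
        minima = find_local_minima(two_basin_truth, ceiling=5.0)
        dec = segment_basins(two_basin_truth, minima)
        s01 = minimax_saddle(two_basin_truth, (minima[0].i, minima[0].j),
                             (minima[1].i, minima[1].j))
        s10 = minimax_saddle(two_basin_truth, (minima[1].i, minima[1].j),
                             (minima[0].i, minima[0].j))
        assert s01 == pytest.approx(s10, abs=1e-12)
        b01 = barrier_height(dec, two_basin_truth, 0, 1)
        b10 = barrier_height(dec, two_basin_truth, 1, 0)
        assert b01 - b10 == pytest.approx(
            minima[1].value - minima[0].value, abs=1e-12)

    def test_masked_region_unreachable(self):
        v = np.zeros((8, 8))
        fes = surface(v + np.linspace(0, 1, 8)[:, None])
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, :] = True
        mask[0, :] = True  # periodic wrap blocked too
        with pytest.raises(ValueError, match="unreachable"):
            minimax_saddle(fes, (2, 2), (6, 6), mask=mask)


class TestQuadrant:
    @pytest.mark.parametrize("phi,psi,want", [
        (-77.5, 132.5, ("-", "+")),
        (82.5, 95.0, ("+", "+")),
        (-97.5, -80.0, ("-", "-")),
        (0.0, -1.0, ("+", "-")),
    ])
    def test_examples(self, phi, psi, want):
        assert quadrant(phi, psi) == want


class TestExtent:
    def test_circular_well_matches_analytic_contour(self):
        depth, kappa = 6.0, 5.0
        p = ToyPotential(wells=((0.0, 0.0, depth, kappa),))
        fes = potential_grid(p, nbins=144)
        minima = find_local_minima(fes, ceiling=5.0)
        dec = segment_basins(fes, minima, ceiling=1e9)
        level = depth / 2.0
        (plo, phi_), (qlo, qhi) = basin_extent(dec, fes, 0, level)
        # analytic contour: depth*(1-exp(kappa(cos dx - 1))) = level on axis
        r = np.degrees(np.arccos(1 + np.log(1 - level / depth) / kappa))
        assert plo == pytest.approx(-r, abs=2.5)
        assert phi_ == pytest.approx(r, abs=2.5)
        assert qlo == pytest.approx(-r, abs=2.5)

    def test_infinite_level_full_span(self):
        v = np.zeros((12, 12))
        v[0, 0] = -1.0
        fes = surface(v)
        minima = find_local_minima(fes, ceiling=np.inf)
        dec = segment_basins(fes, minima, ceiling=np.inf)
        ext = basin_extent(dec, fes, 0, np.inf)
        assert ext == ((-180.0, 180.0), (-180.0, 180.0))

    def test_wrap_straddling_interval(self):
        p = ToyPotential(wells=((180.0, 0.0, 6.0, 6.0),))
        fes = potential_grid(p, nbins=72)
        minima = find_local_minima(fes, ceiling=5.0)
        dec = segment_basins(fes, minima, ceiling=1e9)
        (plo, phi_), _ = basin_extent(dec, fes, 0, 3.0)
        assert plo > phi_  # single interval crossing the +/-180 seam

    def test_level_below_minimum_empty(self, two_basin_truth):
        minima = find_local_minima(two_basin_truth, ceiling=5.0)
        dec = segment_basins(two_basin_truth, minima)
        ext = basin_extent(dec, two_basin_truth, 1, 0.5)  # secondary at 1.5
        assert all(np.isnan(v) for iv in ext for v in iv)


class TestReplicates:
    def test_identical_surfaces_consistent(self, two_basin_truth):
        rep = compare_replicates([two_basin_truth, two_basin_truth])
        assert rep["rms_low_region"] == 0.0
        assert rep["consistent"]

    def test_constant_offset_vanishes_after_normalization(self, two_basin_truth):
        shifted = normalize_min_zero(FreeEnergySurface(
            grid=PeriodicGrid2D(values=two_basin_truth.values + 2.0)))
        rep = compare_replicates([two_basin_truth, shifted])
        assert rep["rms_low_region"] == pytest.approx(0.0, abs=1e-12)

    def test_argmin_in_other_quadrant_inconsistent(self, two_basin, two_basin_truth):
        from gagfes.toy import design_two_basin, potential_grid
        flipped = design_two_basin(6.0, 4.5, 4.0,
                                   centers=((-97.5, -80.0), (-77.5, 132.5)))
        rep = compare_replicates([two_basin_truth, potential_grid(flipped)])
        assert not rep["consistent"]

    def test_grid_mismatch_rejected(self, two_basin, two_basin_truth):
        from gagfes.toy import potential_grid
        other = potential_grid(two_basin, nbins=72)
        with pytest.raises(ValueError):
            compare_replicates([two_basin_truth, other])


class TestMinShift:
    def test_identical_zero(self, two_basin_truth):
        assert min_shift(two_basin_truth, two_basin_truth) == (0.0, 0.0)

    def test_pucker_shift_arithmetic(self):
        """Shift between chair-like and twist-boat-like global minima of
        the flexible-linkage landscape: (-77.5, 132.5) -> (-55, 135)."""
        a = potential_grid(ToyPotential(wells=((-77.5, 132.5, 5.0, 6.0),)))
        b = potential_grid(ToyPotential(wells=((-55.0, 135.0, 5.0, 6.0),)))
        assert min_shift(a, b) == (22.5, 2.5)

    def test_wrap_minimal_image(self):
        a = potential_grid(ToyPotential(wells=((-177.5, 0.0, 5.0, 6.0),)))
        b = potential_grid(ToyPotential(wells=((177.5, 0.0, 5.0, 6.0),)))
        assert min_shift(a, b) == (-5.0, 0.0)


class TestCrop:
    def test_crop_preserves_values_and_full_range_identity(self, two_basin_truth):
        from gagfes.fes import value_at
        crop = crop_phi_report(two_basin_truth, (-180.0, 0.0))
        k = np.where(crop["phi"] == -77.5)[0][0]
        jj = np.where(crop["psi"] == 132.5)[0][0]
        assert crop["values"][k, jj] == value_at(two_basin_truth, -77.5, 132.5)
        full = crop_phi_report(two_basin_truth, (-180.0, 180.0))
        assert full["values"].shape == two_basin_truth.values.shape

    def test_minima_outside_crop_still_found(self, two_basin_truth):
        crop = crop_phi_report(two_basin_truth, (-90.0, -60.0))
        minima = find_local_minima(two_basin_truth, ceiling=5.0)
        assert len(minima) == 2  # full-torus analysis unaffected by crops
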