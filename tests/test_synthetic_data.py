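"""Synthetic-data generators: areas, determinism, conservation, physics."""

import numpy as np
import pytest

from afforwet import (
    InfeasibleAllocationError,
    bucket_soil_moisture,
    gen_basins,
    gen_climate,
    gen_forest_history,
    gen_observed_wetlands,
    gen_rice_mask,
    gen_wetland_params,
    make_grid_domain,
)
from afforwet.synthetic_data import ClimateFields, ForestTrajectory, allocate_with_caps


class TestGridDomain:
    def test_midlatitude_cell_area(self):
        """A 0.5-degree cell at 36N covers ~2500 km^2."""
        d = make_grid_domain(1, 1, lat0=36.0, resolution=0.5)
        assert d.cell_area[0, 0] == pytest.approx(2500.0, rel=0.05)

    def test_equatorial_cell_area(self):
        # R^2 * dlon * (sin(0.25) - sin(-0.25)) with R = 6371 km
        d = make_grid_domain(1, 1, lat0=0.0, resolution=0.5)
        assert d.cell_area[0, 0] == pytest.approx(3091.07, abs=0.5)

    def test_area_varies_only_with_latitude(self):
        d = make_grid_domain(2, 2, lat0=30.0, resolution=0.5)
        assert d.cell_area.shape == (2, 2)
        assert np.all(d.cell_area[:, 0] == d.cell_area[:, 1])
        assert d.cell_area[0, 0] != d.cell_area[1, 0]

    @pytest.mark.parametrize("kw", [dict(n_lat=0), dict(n_lon=0), dict(resolution=-0.5)])
    def test_invalid_arguments(self, kw):
        args = dict(n_lat=2, n_lon=2, lat0=30.0, resolution=0.5)
        args.update(kw)
        with pytest.raises(ValueError):
            make_grid_domain(**args)


class TestClimate:
    def test_same_seed_bit_identical(self, small_domain):
        a = gen_climate(small_domain, seed=7)
        b = gen_climate(small_domain, seed=7)
        assert np.array_equal(a.P, b.P) and np.array_equal(a.PET, b.PET)

    def test_aridity_gradient_strictly_increasing(self, small_domain):
        c = gen_climate(small_domain, seed=3, phi_range=(0.3, 3.0))
        col_means = c.phi.mean(axis=(0, 1))
        assert np.all(np.diff(col_means) > 0)

    def test_all_three_zones_present(self, small_domain):
        c = gen_climate(small_domain, seed=3, phi_range=(0.3, 3.0))
        phi = c.phi_mean
        assert (phi < 1).any() and ((phi >= 1) & (phi <= 2)).any() and (phi > 2).any()

    def test_zero_cv_means_identical_years(self, small_domain):
        c = gen_climate(small_domain, seed=1, interannual_cv=0.0)
        assert np.all(c.P == c.P[0]) and np.all(c.PET == c.PET[0])

    def test_empty_phi_range_rejected(self, small_domain):
        with pytest.raises(ValueError):
            gen_climate(small_domain, seed=1, phi_range=(0.0, 1.0))


class TestForestHistory:
    def test_zero_increase_constant(self, small_domain):
        f = gen_forest_history(small_domain, seed=1, national_increase_km2=0.0)
        assert np.all(f.forest_frac == f.forest_frac[0])

    def test_conservation(self, small_domain):
        target = 5000.0
        f = gen_forest_history(small_domain, seed=2, national_increase_km2=target)
        planted = f.planted_area_km2.sum()
        assert planted == pytest.approx(target, rel=1e-3)

    def test_monotone_piecewise_linear(self, small_domain):
        f = gen_forest_history(small_domain, seed=2, national_increase_km2=5000.0)
        assert np.all(np.diff(f.forest_frac, axis=0) >= -1e-15)
        # linear ramp: second differences vanish
        assert np.allclose(np.diff(f.forest_frac, n=2, axis=0), 0.0, atol=1e-12)

    def test_single_cell_arithmetic(self):
        """250 km^2 planted on a ~2500 km^2 cell raises the fraction by 0.1."""
        d = make_grid_domain(1, 1, lat0=36.0, resolution=0.5)
        f = gen_forest_history(
            d, seed=0, national_increase_km2=250.0,
            start_year=2000, end_year=2016, initial_frac_range=(0.1, 0.1),
        )
        rise = f.forest_frac[-1, 0, 0] - f.forest_frac[0, 0, 0]
        assert rise == pytest.approx(250.0 / d.cell_area[0, 0])
        assert rise == pytest.approx(0.1, rel=0.01)

    def test_infeasible_target_raises(self, small_domain):
        too_much = small_domain.total_area_km2 * 2
        with pytest.raises(InfeasibleAllocationError):
            gen_forest_history(small_domain, seed=1, national_increase_km2=too_much)


def test_allocate_with_caps_redistributes():
    weights = np.array([10.0, 1.0, 1.0])
    capacity = np.array([5.0, 100.0, 100.0])
    alloc = allocate_with_caps(50.0, weights, capacity)
    assert alloc.sum() == pytest.approx(50.0)
    assert alloc[0] == pytest.approx(5.0)  # capped, excess moved elsewhere
    shortfall = 300.0 - capacity.sum()
    with pytest.raises(InfeasibleAllocationError) as err:
        allocate_with_caps(300.0, weights, capacity)
    assert err.value.shortfall_km2 == pytest.approx(shortfall)


class TestBucket:
    def _flat_climate(self, domain, phi, p=800.0, n_years=3):
        years = np.arange(2000, 2000 + n_years)
        shape = (n_years, domain.n_lat, domain.n_lon)
        P = np.full(shape, p)
        return ClimateFields(P=P, PET=phi * P, years=years, domain=domain)

    def _constant_forest(self, domain, frac, years):
        arr = np.broadcast_to(
            np.asarray(frac, dtype=float),
            (len(years), domain.n_lat, domain.n_lon),
        ).copy()
        return ForestTrajectory(forest_frac=arr, years=np.asarray(years), domain=domain)

    def test_no_rain_decays_to_zero(self):
        d = make_grid_domain(1, 1)
        c = self._flat_climate(d, phi=1.0, p=1e-9, n_years=5)
        f = self._constant_forest(d, 0.3, c.years)
        sm = bucket_soil_moisture(c, f)
        assert np.all(np.diff(sm.sm[:, 0, 0]) <= 0)
        assert sm.sm[-1, 0, 0] < sm.sm[0, 0, 0]

    def test_budget_closes_on_unclamped_steps(self, std):
        sm = std.sm_s1
        inner = (sm.sm > 0) & (sm.sm < sm.sm_sat)
        resid = (sm.sm - sm.sm_prev) - (sm.p_flux - sm.et_flux - sm.q_flux)
        assert np.abs(resid[inner]).max() < 1e-9

    def test_more_forest_means_drier_soil(self):
        """At PET/P = 2 a 50%-forest cell holds less water than a 10% one."""
        d = make_grid_domain(1, 2)
        c = self._flat_climate(d, phi=2.0, n_years=4)
        f = self._constant_forest(d, np.array([[0.1, 0.5]]), c.years)
        sm = bucket_soil_moisture(c, f)
        assert sm.sm[:, 0, 1].mean() < sm.sm[:, 0, 0].mean()

    def test_domain_mismatch_rejected(self, small_domain):
        d = make_grid_domain(1, 1)
        c = self._flat_climate(d, phi=1.0)
        f = self._constant_forest(small_domain, 0.2, c.years)
        with pytest.raises(ValueError, match="mismatch"):
            bucket_soil_moisture(c, f)


class TestObservedWetlands:
    def test_zero_noise_reproducible_and_dominated(self, std):
        from afforwet import soil_moisture_deficit, wetland_fraction
        from afforwet.wetland_diagnostic import annual_max_fraction

        obs = gen_observed_wetlands(std.true_params, std.sm_s1, noise_cv=0.0, seed=9)
        frac = wetland_fraction(soil_moisture_deficit(std.sm_s1), std.true_params)
        ann = annual_max_fraction(frac, std.sm_s1.years.size)
        assert np.allclose(obs.annual_max_frac, ann)
        assert np.all(obs.static_max_frac >= ann.max(axis=0) - 1e-12)

    def test_same_seed_same_noise(self, std):
        a = gen_observed_wetlands(std.true_params, std.sm_s1, 0.05, seed=4)
        b = gen_observed_wetlands(std.true_params, std.sm_s1, 0.05, seed=4)
        assert np.array_equal(a.annual_max_frac, b.annual_max_frac)


class TestBasins:
    def test_partition_and_contiguity(self, small_domain):
        bt = gen_basins(small_domain, n_basins=5, seed=11)
        assert bt.basin_area_km2().sum() == pytest.approx(small_domain.total_area_km2)
        assert set(np.unique(bt.basin_id)) == set(range(5))
        # contiguity: flood-fill each basin from one member reaches all members
        for b in range(5):
            cells = {tuple(c) for c in np.argwhere(bt.basin_id == b)}
            seen, stack = set(), [next(iter(cells))]
            while stack:
                i, j = stack.pop()
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                    if (ni, nj) in cells and (ni, nj) not in seen:
                        stack.append((ni, nj))
            assert seen == cells

    def test_every_cell_its_own_basin(self, small_domain):
        bt = gen_basins(small_domain, n_basins=small_domain.n_cells, seed=1)
        assert np.unique(bt.basin_id).size == small_domain.n_cells

    def test_all_unprotected(self, small_domain):
        bt = gen_basins(small_domain, 4, level_shares={"unprotected": 1.0}, seed=2)
        assert set(bt.levels.values()) == {"unprotected"}

    def test_invalid_counts(self, small_domain):
        with pytest.raises(ValueError):
            gen_basins(small_domain, 0, seed=1)


class TestRiceMask:
    def test_zero_probability_all_zero(self, small_domain):
        assert np.all(gen_rice_mask(small_domain, seed=1, rice_prob=0.0) == 0)

    def test_nonzero_cells_within_range(self, small_domain):
        m = gen_rice_mask(small_domain, seed=5, rice_prob=0.5, rice_frac_range=(0.1, 0.3))
        nz = m[m > 0]
        assert nz.size > 0 and np.all((nz >= 0.1) & (nz <= 0.3))

    def test_deterministic(self, small_domain):
        a = gen_rice_mask(small_domain, seed=8)
        b = gen_rice_mask(small_domain, seed=8)
        assert np.array_equal(a, b)


def test_wetland_params_ground_truth(small_domain):
    p = gen_wetland_params(small_domain, seed=3)
    f = np.asarray(p.f_max)
    assert ((f == 0) | ((f >= 0.05) & (f <= 0.4))).all()
    assert (f == 0).any() and (f > 0).any()
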