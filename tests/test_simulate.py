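"""Synthetic generator: determinism, constructed spatial structure, and the
statistical properties downstream recovery experiments rely on."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from trisoscape import (
    DomainError,
    SyntheticConfig,
    forward_cellulose,
    gen_climate_grid,
    gen_d18op_field,
    gen_sites,
    gen_stations,
    pearson,
    standardize_species,
)
from trisoscape.simulate import ism_lapse_mask

from conftest import small_config


def _full(cfg):
    return gen_d18op_field(cfg, gen_climate_grid(cfg))


class TestDeterminism:
    def test_same_seed_gives_bit_identical_outputs(self):
        a, b = (_full(small_config(seed=7)) for _ in range(2))
        xr.testing.assert_identical(a.ds, b.ds)
        sa, sb = (gen_sites(small_config(seed=7), a) for _ in range(2))
        pd.testing.assert_frame_equal(sa, sb)
        ta, tb = (gen_stations(small_config(seed=7), a) for _ in range(2))
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seeds_differ(self):
        a = _full(small_config(seed=0))
        b = _full(small_config(seed=1))
        assert not np.allclose(a.var("tmean").values, b.var("tmean").values)


class TestClimateGrid:
    def test_rh_within_physical_bounds(self):
        grid = _full(small_config())
        rh = grid.var("rh").values
        assert rh.min() >= 20.0 - 1e-9 and rh.max() <= 100.0

    def test_doubling_noise_sd_doubles_the_noise_component(self):
        # noise enters as sd * unit-variance field, so same-seed fields scale exactly
        base = gen_climate_grid(small_config(t_noise_sd=0.0, rh_noise_sd=0.0))
        one = gen_climate_grid(small_config(t_noise_sd=0.5, rh_noise_sd=0.0))
        two = gen_climate_grid(small_config(t_noise_sd=1.0, rh_noise_sd=0.0))
        n1 = one.var("tmean").values - base.var("tmean").values
        n2 = two.var("tmean").values - base.var("tmean").values
        assert np.allclose(n2, 2.0 * n1)
        assert np.std(n2) == pytest.approx(2.0 * np.std(n1))

    def test_degenerate_grid_raises(self):
        with pytest.raises(DomainError):
            gen_climate_grid(small_config(lon_max=60.5, step=1.0))


class TestD18OPField:
    def test_band_mean_ordering_mid_above_low_and_high(self):
        grid = _full(small_config())
        pm = grid.seasonal_mean("d18op")
        low = float(pm.sel(lat=slice(None, 30)).mean())
        mid = float(pm.sel(lat=slice(30, 50)).mean())
        high = float(pm.sel(lat=slice(50, None)).mean())
        assert mid > low and mid > high

    def test_configured_band_means_recovered_exactly_at_zero_noise(self):
        cfg = small_config(
            band_means=(-6.0, -2.0, -8.0), d18op_noise_sd=0.0, lapse_per_100m=0.0
        )
        pm = _full(cfg).seasonal_mean("d18op")
        assert float(pm.sel(lat=slice(None, 30)).mean()) == pytest.approx(-6.0, abs=1e-12)
        assert float(pm.sel(lat=slice(30, 50)).mean()) == pytest.approx(-2.0, abs=1e-12)
        assert float(pm.sel(lat=slice(50, None)).mean()) == pytest.approx(-8.0, abs=1e-12)

    def test_zero_noise_ism_elevation_regression_recovers_lapse_exactly(self):
        cfg = small_config(d18op_noise_sd=0.0)
        grid = _full(cfg)
        lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
        mask = ism_lapse_mask(cfg, lat2, lon2)
        elev = grid.var("elevation").values[mask]
        p = grid.seasonal_mean("d18op").values[mask]
        slope = np.polyfit(elev, p, 1)[0] * 100.0
        assert slope == pytest.approx(cfg.lapse_per_100m, abs=1e-9)

    def test_band_edges_outside_lat_bounds_raise(self):
        with pytest.raises(DomainError):
            small_config(band_edges=(30.0, 75.0))

    def test_may_sep_mean_free_of_the_seasonal_cycle(self):
        # seasonal harmonic is centred on the growing season: its May-Sep mean is 0
        cfg = small_config(
            d18op_noise_sd=0.0, lapse_per_100m=0.0, band_means=(-5.0, -5.0, -5.0)
        )
        grid = _full(cfg)
        monthly = grid.var("d18op")
        ms = monthly.sel(month=slice(5, 9)).mean("month").values
        assert np.allclose(ms, -5.0, atol=1e-12)
        # but individual months do carry the seasonal cycle
        assert float(monthly.sel(month=1).std()) < 1e-12 and float(monthly.std()) > 0.1


class TestSites:
    def test_zero_noise_conifers_equal_the_forward_model(self):
        cfg = small_config(site_noise_sd=0.0, broadleaf_fraction=0.0)
        grid = _full(cfg)
        sites = gen_sites(cfg, grid)
        expected = forward_cellulose(sites["d18o_p_true"], sites["rh_true"])
        assert np.allclose(sites["d18o_tr_permil"], expected, atol=1e-12)

    def test_broadleaf_depleted_then_standardization_restores(self):
        cfg = small_config(site_noise_sd=0.0, broadleaf_fraction=1.0)
        sites = gen_sites(cfg, _full(cfg))
        # raw broadleaf records sit 1.9 permil below the species-free value
        assert np.allclose(
            sites["d18o_tr_permil"], sites["d18o_tr_true"] - 1.9, atol=1e-12
        )
        std = standardize_species(sites)
        assert np.allclose(std["d18o_tr_std"], std["d18o_tr_true"], atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_observed_range_within_the_continental_envelope(self, seed):
        cfg = SyntheticConfig(seed=seed)
        sites = gen_sites(cfg, _full(cfg))
        tr = sites["d18o_tr_permil"]
        assert tr.min() > 15.0 and tr.max() < 38.0

    def test_too_few_sites_raises(self):
        with pytest.raises(DomainError):
            small_config(n_sites=1)

    def test_sites_require_rh_and_d18op_fields(self):
        cfg = small_config()
        with pytest.raises(DomainError):
            gen_sites(cfg, gen_climate_grid(cfg))  # no d18op yet


class TestStations:
    def test_station_count_matches_config(self):
        cfg = small_config()
        assert len(gen_stations(cfg, _full(cfg))) == cfg.n_stations

    def test_zero_noise_station_mean_equals_grid_cell_value(self):
        cfg = small_config(station_noise_sd=0.0)
        grid = _full(cfg)
        stn = gen_stations(cfg, grid)
        pm = grid.seasonal_mean("d18op")
        cell = pm.sel(
            lat=xr.DataArray(stn["lat"].to_numpy(), dims="s"),
            lon=xr.DataArray(stn["lon"].to_numpy(), dims="s"),
            method="nearest",
        ).values
        assert np.allclose(stn["d18o_p_may_sep"], cell, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_station_means_within_the_observed_envelope(self, seed):
        cfg = SyntheticConfig(seed=seed)
        stn = gen_stations(cfg, _full(cfg))
        m = stn["d18o_p_may_sep"]
        assert m.min() > -20.0 and m.max() < 3.0


class TestSignStructure:
    @pytest.mark.parametrize("seed", range(10))
    def test_site_correlations_have_the_expected_signs(self, seed):
        cfg = SyntheticConfig(seed=seed)
        sites = gen_sites(cfg, _full(cfg))
        tr = sites["d18o_tr_permil"]
        assert pearson(sites["d18o_p_true"], tr).r > 0.3
        assert pearson(sites["rh_true"], tr).r < -0.3
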