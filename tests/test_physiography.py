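import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from paleogradient.grid import GridSpec
from paleogradient.physiography import (
    COARSE_BAND,
    FINE_BAND,
    ScaleBand,
    categorize_flux,
    categorize_slope,
    categorize_tpi,
    compute_physiography,
    compute_slope,
    compute_tpi,
    hydro_categories,
    physiographic_diversity,
    standardize_tpi,
)


from oracles import brute_force_tpi


class TestTPI:
    def test_constant_field_is_zero(self):
        elev = np.full((6, 8), 42.0)
        land = np.ones((6, 8), dtype=bool)
        tpi = compute_tpi(elev, FINE_BAND, land)
        assert np.allclose(tpi, 0.0)

    def test_peak_of_unit_height(self):
        elev = np.zeros((5, 7))
        elev[2, 3] = 1.0
        land = np.ones((5, 7), dtype=bool)
        tpi = compute_tpi(elev, FINE_BAND, land)
        assert tpi[2, 3] == pytest.approx(1.0)

    @pytest.mark.parametrize("band", [FINE_BAND, COARSE_BAND])
    def test_matches_brute_force_on_random_fields(self, band, rng):
        for _ in range(3):
            elev = rng.normal(0, 500, (8, 8))
            land = rng.random((8, 8)) < 0.7
            got = compute_tpi(elev, band, land)
            want = brute_force_tpi(elev, band, land)
            assert np.array_equal(np.isnan(got), np.isnan(want))
            ok = ~np.isnan(want)
            assert np.allclose(got[ok], want[ok])

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ScaleBand(2, 2)


class TestStandardize:
    def test_identity_mean_zero_sd_hundred(self, rng):
        tpi = rng.normal(0, 3, (10, 10))
        out, flag = standardize_tpi(tpi)
        assert not flag
        assert abs(out.mean()) < 1e-9
        assert out.std() == pytest.approx(100.0, abs=1e-6)

    def test_flat_field_flagged(self):
        out, flag = standardize_tpi(np.full((4, 4), 7.0))
        assert flag
        assert np.allclose(out, 0.0)

    def test_two_valued_field_maps_to_plus_minus_hundred(self):
        tpi = np.array([[-3.0, 3.0]] * 4)
        out, _ = standardize_tpi(tpi)
        assert set(np.round(out.ravel(), 9)) == {-100.0, 100.0}


class TestSlope:
    def test_flat_is_zero(self, tiny_grid):
        elev = np.zeros(tiny_grid.shape)
        s = compute_slope(elev, tiny_grid)
        assert np.allclose(s, 0.0)

    def test_known_rise_over_run(self):
        # 100 m rise over a 100 km cell span -> arctan(0.001) ~ 0.0573 deg
        g = GridSpec(0.9, 0.9)  # ~100 km meridional span
        elev = np.zeros(g.shape)
        elev[g.nlat // 2, :] = 100.0
        land = np.zeros(g.shape, dtype=bool)
        land[g.nlat // 2 - 1: g.nlat // 2 + 1, :] = True
        s = compute_slope(elev, g, land)
        run = 6371e3 * np.deg2rad(0.9)
        expect = np.degrees(np.arctan(100.0 / run))
        assert s[g.nlat // 2, 0] == pytest.approx(expect, rel=1e-6)

    def test_translation_invariance(self, tiny_grid, rng):
        elev = rng.normal(0, 300, tiny_grid.shape)
        a = compute_slope(elev, tiny_grid)
        b = compute_slope(elev + 1234.5, tiny_grid)
        assert np.allclose(a, b)


class TestCategories:
    @pytest.mark.parametrize(
        "slope,cat",
        [(0.0, 1), (0.029, 1), (0.03, 2), (0.2, 3), (0.3, 4), (5.0, 10)],
    )
    def test_slope_thresholds(self, slope, cat):
        assert categorize_slope(np.array([slope]))[0] == cat

    @pytest.mark.parametrize(
        "flux,cat",
        [(0.0, 1), (10**6.5, 1), (10**7.5, 2), (10**8.5, 3), (10**9.5, 4), (1e11, 5)],
    )
    def test_flux_thresholds(self, flux, cat):
        assert categorize_flux(np.array([flux]))[0] == cat

    def test_negative_discharge_rejected(self):
        with pytest.raises(ValueError):
            categorize_flux(np.array([-1.0]))

    def test_full_log_range_gives_exactly_five_hydro_classes(self, rng):
        disc = 10 ** rng.uniform(5, 12, 400)
        h = hydro_categories(disc)
        assert set(h.tolist()) == {1, 2, 3, 4, 5}

    def test_hydro_monotone_in_discharge(self):
        d = np.logspace(4, 12, 200)
        h = hydro_categories(d)
        assert np.all(np.diff(h) >= 0)

    def test_tpi_deciles_balanced(self, rng):
        vals = rng.normal(0, 100, (20, 20))
        cat = categorize_tpi(vals)
        counts = np.bincount(cat.ravel(), minlength=11)[1:]
        assert counts.min() >= 30  # ~40 per decile on 400 cells
        assert set(np.unique(cat)) == set(range(1, 11))


class TestPhi:
    def test_constant_layers_give_zero(self):
        one = np.ones((5, 5), dtype=np.int64)
        phi = physiographic_diversity(one, one, one, radius=1)
        assert np.allclose(phi, 0.0)

    def test_uniform_types_give_one(self):
        # window of 9 cells, 3 categories per variable, perfectly even
        base = np.arange(9).reshape(3, 3) % 3 + 1
        layer = np.tile(base, (3, 3)).astype(np.int64)
        phi = physiographic_diversity(layer, layer, layer, radius=1,
                                      n_categories=(3, 3, 3))
        # interior cells see each type 3 times in 9 cells
        assert phi[4, 4] == pytest.approx(1.0)

    def test_two_of_ten_worked_example(self):
        # a neighbourhood with two equally frequent of 10 TPI types and
        # the other variables constant: Φ = (ln2/ln10 + 0 + 0)/3 ≈ 0.1003
        tpi = np.zeros((3, 3), dtype=np.int64)  # 0 = sea
        tpi[1, 0], tpi[1, 1] = 1, 2
        slope = np.where(tpi > 0, 4, 0).astype(np.int64)
        flux = np.where(tpi > 0, 2, 0).astype(np.int64)
        phi = physiographic_diversity(tpi, slope, flux, radius=1)
        expect = (np.log(2) / np.log(10)) / 3
        assert phi[1, 0] == pytest.approx(expect, abs=1e-12)
        assert phi[1, 1] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.1003, abs=5e-4)

    def test_sea_window_masked_and_coast_clipped(self):
        tpi = np.zeros((4, 4), dtype=np.int64)  # 0 = sea
        tpi[1, 1] = 3
        slope = tpi.copy()
        flux = np.where(tpi > 0, 1, 0).astype(np.int64)
        phi = physiographic_diversity(tpi, slope, flux, radius=1)
        assert np.isnan(phi[3, 3])
        assert phi[1, 1] == pytest.approx(0.0)  # single observation

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        tpi=hnp.arrays(np.int64, (6, 6), elements=st.integers(1, 10)),
        slope=hnp.arrays(np.int64, (6, 6), elements=st.integers(1, 10)),
        flux=hnp.arrays(np.int64, (6, 6), elements=st.integers(1, 5)),
    )
    def test_phi_bounded_zero_one(self, tpi, slope, flux):
        phi = physiographic_diversity(tpi, slope, flux, radius=1)
        ok = np.isfinite(phi)
        assert np.all(phi[ok] >= -1e-12)
        assert np.all(phi[ok] <= 1 + 1e-12)


def test_full_pipeline_layers_consistent(tiny_world):
    sl = tiny_world.slice(0)
    layers = compute_physiography(sl["elevation"], sl["discharge"],
                                  sl["land"], tiny_world.grid)
    land = sl["land"]
    assert np.all(layers.tpi_cat[land] >= 1) and np.all(layers.tpi_cat[land] <= 10)
    assert np.all(layers.slope_cat[land] >= 1) and np.all(layers.slope_cat[land] <= 10)
    assert np.all(layers.hydro[land] >= 1) and np.all(layers.hydro[land] <= 5)
    ok = np.isfinite(layers.phi)
    assert np.all(layers.phi[ok] >= 0) and np.all(layers.phi[ok] <= 1)
    assert not np.isfinite(layers.phi[~land]).any()
    # standardization identity holds for the averaged TPI_S map
    assert abs(np.nanmean(layers.tpi_s)) < 25.0
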