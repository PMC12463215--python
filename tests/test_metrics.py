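import numpy as np
import pandas as pd
import pytest

from paleogradient.ecoevo.simulation import Event, SimulationRecord
from paleogradient.grid import GridSpec
from paleogradient.metrics import (
    DiversitySummary,
    ensemble_average,
    event_grids,
    latitudinal_profile,
    rates,
    spearman_compare,
)


def record_from(grid, richness, events, spinup=0):
    rec = SimulationRecord(
        grid=grid,
        ages=np.arange(richness.shape[0] - 1, -1, -1, dtype=float),
        scenario_id="M0", seed=0,
        richness=richness.astype(np.int32),
        events=events,
        spinup_steps=spinup,
    )
    orig = rec.counts_per_step("origination")
    ext = rec.counts_per_step("extinction")
    rec.extant_counts = np.cumsum(orig - ext)
    return rec


@pytest.fixture(scope="module")
def grid():
    return GridSpec(20.0, 20.0)


class TestEventAttribution:
    def test_weights_conserve_global_counts(self, grid):
        nlat, nlon = grid.shape
        rich = np.ones((4, nlat, nlon))
        events = [
            Event(0, 3.0, "origination", 1, None, (0,)),
            Event(1, 2.0, "origination", 2, 1, (5, 6, 7)),
            Event(2, 1.0, "extinction", 2, 1, (5, 6)),
        ]
        rec = record_from(grid, rich, events)
        spec, ext = event_grids(rec)
        assert spec[1].sum() == pytest.approx(1.0)
        assert ext[2].sum() == pytest.approx(1.0)
        assert spec.sum() == pytest.approx(2.0)

    def test_net_and_turnover_counting(self, grid):
        nlat, nlon = grid.shape
        rich = np.zeros((3, nlat, nlon))
        rich[:, 4, 3] = 2.0
        events = [
            Event(0, 2.0, "origination", 1, None, (4 * nlon + 3,)),
            Event(0, 2.0, "origination", 2, None, (4 * nlon + 3,)),
            Event(1, 1.0, "origination", 3, 1, (4 * nlon + 3,)),
            Event(1, 1.0, "origination", 4, 1, (4 * nlon + 3,)),
            Event(1, 1.0, "extinction", 3, 1, (4 * nlon + 3,)),
        ]
        rec = record_from(grid, rich, events)
        s = rates(rec)
        assert s.fields["net"][1, 4, 3] == pytest.approx(1.0)
        assert s.fields["turnover"][1, 4, 3] == pytest.approx(3.0 / 2.0)

    def test_turnover_masked_where_richness_zero(self, grid):
        nlat, nlon = grid.shape
        rich = np.zeros((2, nlat, nlon))
        rec = record_from(grid, rich, [])
        s = rates(rec)
        assert np.isnan(s.fields["turnover"]).all()

    def test_no_events_step_gives_zero_net(self, grid):
        nlat, nlon = grid.shape
        rich = np.ones((2, nlat, nlon))
        rec = record_from(grid, rich, [])
        s = rates(rec)
        assert np.all(s.fields["net"] == 0.0)
        assert np.all(s.fields["turnover"][np.isfinite(s.fields["turnover"])] == 0)

    def test_inconsistent_bookkeeping_raises(self, grid):
        nlat, nlon = grid.shape
        rec = record_from(grid, np.zeros((2, nlat, nlon)), [])
        rec.extant_counts = np.array([5, 5])
        with pytest.raises(RuntimeError):
            rates(rec)


class TestProfiles:
    def test_uniform_richness_constant_profile(self, grid):
        nlat, nlon = grid.shape
        rich = np.ones((3, nlat, nlon))
        rec = record_from(grid, rich, [])
        s = rates(rec)
        prof = latitudinal_profile(s, "richness", exclude_spinup=False)
        assert np.allclose(prof.to_numpy(dtype=float), 1.0)

    def test_spinup_steps_dropped(self, grid):
        nlat, nlon = grid.shape
        rich = np.ones((30, nlat, nlon))
        rec = record_from(grid, rich, [], spinup=25)
        s = rates(rec)
        prof = latitudinal_profile(s, "richness", exclude_spinup=True)
        assert len(prof) == 5

    def test_normalized_max_is_one_and_idempotent(self, grid, rng):
        nlat, nlon = grid.shape
        rich = rng.random((4, nlat, nlon)) * 7
        rec = record_from(grid, rich, [])
        s = rates(rec)
        prof = latitudinal_profile(s, "richness", exclude_spinup=False)
        vals = prof.to_numpy(dtype=float)
        assert np.nanmax(vals) == pytest.approx(1.0)
        # renormalizing an already-normalized field changes nothing
        s2 = DiversitySummary(grid=s.grid, ages=s.ages,
                              fields={"richness": vals[:, :, None] * np.ones(nlon)},
                              land=np.ones((4, nlat, nlon), dtype=bool))
        prof2 = latitudinal_profile(s2, "richness", exclude_spinup=False)
        assert np.allclose(prof2.to_numpy(dtype=float), vals, equal_nan=True)

    def test_profile_invariant_to_longitude_rotation(self, grid, rng):
        nlat, nlon = grid.shape
        rich = rng.random((3, nlat, nlon))
        land = rng.random((3, nlat, nlon)) < 0.6
        s1 = DiversitySummary(grid=grid, ages=np.arange(2, -1, -1, dtype=float),
                              fields={"richness": rich}, land=land)
        s2 = DiversitySummary(grid=grid, ages=s1.ages,
                              fields={"richness": np.roll(rich, 4, axis=2)},
                              land=np.roll(land, 4, axis=2))
        p1 = latitudinal_profile(s1, "richness", exclude_spinup=False)
        p2 = latitudinal_profile(s2, "richness", exclude_spinup=False)
        assert np.allclose(p1.to_numpy(dtype=float), p2.to_numpy(dtype=float),
                           equal_nan=True)

    def test_band_without_land_masked(self, grid):
        nlat, nlon = grid.shape
        land = np.ones((2, nlat, nlon), dtype=bool)
        land[:, 0, :] = False
        s = DiversitySummary(grid=grid, ages=np.array([1.0, 0.0]),
                             fields={"richness": np.ones((2, nlat, nlon))},
                             land=land)
        prof = latitudinal_profile(s, "richness", exclude_spinup=False)
        assert prof.iloc[:, 0].isna().all()


class TestEnsemble:
    def make_summary(self, grid, field):
        n = field.shape[0]
        return DiversitySummary(
            grid=grid, ages=np.arange(n - 1, -1, -1, dtype=float),
            fields={"richness": field},
            land=np.ones(field.shape, dtype=bool),
        )

    def test_single_record_identity(self, grid, rng):
        f = rng.random((3,) + grid.shape)
        s = self.make_summary(grid, f)
        out = ensemble_average([s])
        assert np.allclose(out.fields["richness"], f)

    def test_mean_of_opposite_patterns(self, grid, rng):
        f = rng.random((3,) + grid.shape)
        a = self.make_summary(grid, 1 + f)
        b = self.make_summary(grid, 1 - f)
        out = ensemble_average([a, b])
        assert np.allclose(out.fields["richness"], 1.0)

    def test_normalize_after_averaging_not_before(self, grid):
        # one member peaks at 10, the other at 1: normalizing first would
        # weight them equally; averaging first must dominate by the big one
        nlat, nlon = grid.shape
        a = np.zeros((2, nlat, nlon)); a[:, 4, 3] = 10.0; a[:, 2, 3] = 5.0
        b = np.zeros((2, nlat, nlon)); b[:, 2, 3] = 1.0
        out = ensemble_average([self.make_summary(grid, a),
                                self.make_summary(grid, b)])
        prof = latitudinal_profile(out, "richness", exclude_spinup=False)
        vals = prof.to_numpy(dtype=float)
        # averaged field: peak 5 at row 4, 3 at row 2 -> normalized 1, 0.6
        assert vals[0][4] == pytest.approx(1.0)
        assert vals[0][2] == pytest.approx(0.6)
        # normalized-then-averaged would have produced 0.75 at row 2
        assert vals[0][2] != pytest.approx(0.75)

    def test_mismatched_grids_rejected(self, grid):
        a = self.make_summary(grid, np.ones((3,) + grid.shape))
        b = self.make_summary(grid, np.ones((4,) + grid.shape))
        with pytest.raises(ValueError):
            ensemble_average([a, b])


class TestSpearman:
    def test_self_correlation_is_one(self, grid, rng):
        r = rng.random(grid.shape)
        latg = grid.lat_grid()
        assert spearman_compare(r, r, latg) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, grid, rng):
        r = rng.random(grid.shape)
        latg = grid.lat_grid()
        assert spearman_compare(r, -r, latg) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        g = GridSpec(36.0, 36.0)
        a = rng.random(g.shape)
        b = rng.random(g.shape)
        latg = g.lat_grid()
        got = spearman_compare(a, b, latg, lat_range=(-90, 90))
        ra = pd.Series(a.ravel()).rank().to_numpy()
        rb = pd.Series(b.ravel()).rank().to_numpy()
        want = np.corrcoef(ra, rb)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)

    def test_latitude_window_restricts_cells(self, grid, rng):
        a = rng.random(grid.shape)
        b = a.copy()
        b[0, :] = -b[0, :]  # corrupt only the 80N band, outside -54..71
        latg = grid.lat_grid()
        assert spearman_compare(a, b, latg) == pytest.approx(1.0)

    def test_too_few_cells_rejected(self, grid):
        a = np.full(grid.shape, np.nan)
        a[4, :5] = 1.0
        with pytest.raises(ValueError):
            spearman_compare(a, a, grid.lat_grid())
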