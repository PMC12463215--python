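import dendropy
import numpy as np
import pytest

from paleogradient.ecoevo import (
    SCENARIOS,
    ParamDraw,
    run_simulation,
    sample_parameters,
    write_phylogeny,
)
from paleogradient.ecoevo.simulation import Event, InitializationError, SimulationRecord
from paleogradient.grid import GridSpec
from paleogradient.world import LandscapeSeries

DRAW = ParamDraw(tau=2.0, omega_t=0.15, omega_p=0.15, shape=2.0, scale=300.0)


def single_cell_world(n_steps=12):
    """One habitable cell forever: no allopatry possible."""
    import xarray as xr

    g = GridSpec(20.0, 20.0)
    nlat, nlon = g.shape
    shape = (n_steps, nlat, nlon)
    land = np.zeros(shape, dtype=np.int8)
    land[:, nlat // 2, 3] = 1
    elev = np.where(land, 500.0, -500.0)
    temp = np.broadcast_to(
        15.0 * np.cos(np.deg2rad(g.lat))[None, :, None], shape
    ).copy()
    prec = np.full(shape, 1.0)
    disc = np.where(land, 1e8, np.nan)
    ds = xr.Dataset(
        {
            "elevation": (("time", "lat", "lon"), elev.astype(float)),
            "temperature": (("time", "lat", "lon"), temp),
            "precipitation": (("time", "lat", "lon"), prec),
            "discharge": (("time", "lat", "lon"), disc),
            "land": (("time", "lat", "lon"), land),
        },
        coords={
            "time": np.arange(n_steps - 1, -1, -1, dtype=float),
            "lat": g.lat,
            "lon": g.lon,
        },
        attrs={"lon_res": 20.0, "lat_res": 20.0},
    )
    return LandscapeSeries(ds)


class TestRunSimulation:
    def test_single_habitable_cell_stays_one_species(self):
        w = single_cell_world()
        rec = run_simulation(w, SCENARIOS["M0"], DRAW, seed=1)
        assert len(rec.species) == 1
        assert np.all(rec.extant_counts == 1)
        assert rec.richness.max() == 1

    def test_executes_every_step(self, tiny_world):
        rec = run_simulation(tiny_world, SCENARIOS["M1e"], DRAW, seed=3)
        assert rec.n_steps == tiny_world.n_steps
        assert rec.richness.shape[0] == tiny_world.n_steps

    def test_bookkeeping_every_step(self, tiny_world):
        rec = run_simulation(tiny_world, SCENARIOS["M1e"], DRAW, seed=3)
        orig = rec.counts_per_step("origination")
        ext = rec.counts_per_step("extinction")
        assert np.array_equal(np.cumsum(orig - ext), rec.extant_counts)

    def test_richness_recounts_from_occupancy(self, tiny_world):
        rec = run_simulation(tiny_world, SCENARIOS["M1e"], DRAW, seed=3)
        # final step: recount from the species states directly
        recount = np.zeros(tiny_world.grid.shape, dtype=np.int32)
        for s in rec.species.values():
            if s.extant:
                for c in s.n:
                    recount.ravel()[c] += 1
        assert np.array_equal(recount, rec.richness[-1])

    def test_deterministic_for_fixed_seed(self, tiny_world):
        a = run_simulation(tiny_world, SCENARIOS["M1s"], DRAW, seed=11)
        b = run_simulation(tiny_world, SCENARIOS["M1s"], DRAW, seed=11)
        assert np.array_equal(a.richness, b.richness)
        assert a.event_table().equals(b.event_table())

    def test_sea_initialization_rejected(self, tiny_world):
        sea = np.argwhere(~tiny_world.land[0])[0]
        with pytest.raises(InitializationError):
            run_simulation(tiny_world, SCENARIOS["M0"], DRAW, seed=1,
                           init=[(int(sea[0]), int(sea[1]))])

    def test_m0_never_computes_physiography(self, tiny_world, monkeypatch):
        import paleogradient.ecoevo.simulation as sim

        def boom(*a, **k):
            raise AssertionError("physiography leaked into M0")

        monkeypatch.setattr(sim, "compute_physiography", boom)
        rec = run_simulation(tiny_world, SCENARIOS["M0"], DRAW, seed=5)
        assert rec.scenario_id == "M0"

    def test_abundances_within_bounds_at_end(self, tiny_world):
        rec = run_simulation(tiny_world, SCENARIOS["M1e"], DRAW, seed=3)
        for s in rec.species.values():
            if s.extant:
                vals = np.array(list(s.n.values()))
                assert np.all(vals >= 0.01 - 1e-12)
                assert np.all(vals <= 1.0 + 1e-9)


class TestDispersalKernel:
    def test_weibull_survival_beyond_1750km(self):
        # P(r > 1750 | shape 2, scale 600) = exp(-(35/12)^2) ~ 1.98e-4
        rng = np.random.default_rng(5)
        n = 10**6
        draws = 600.0 * rng.weibull(2.0, n)
        p_true = np.exp(-((1750.0 / 600.0) ** 2))
        frac = (draws > 1750.0).mean()
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(frac - p_true) < 3 * se
        assert p_true == pytest.approx(1.98e-4, rel=0.03)

    def test_weibull_median(self):
        assert 600.0 * np.log(2) ** 0.5 == pytest.approx(499.6, abs=0.1)

    def test_no_colonization_when_draw_short(self):
        # single occupied cell, nearest neighbour beyond every draw
        w = single_cell_world()
        rec = run_simulation(
            w, SCENARIOS["M0"],
            ParamDraw(tau=2.0, omega_t=0.15, omega_p=0.15, shape=3.0, scale=100.0),
            seed=2,
        )
        occupied = {c for s in rec.species.values() for c in s.n}
        assert len(occupied) == 1


class TestPhylogeny:
    def test_single_species_tree_spans_run(self, tiny_world):
        w = single_cell_world(n_steps=15)
        rec = run_simulation(w, SCENARIOS["M0"], DRAW, seed=1)
        nwk = write_phylogeny(rec)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = tree.leaf_nodes()
        assert len(leaves) == 1
        assert leaves[0].edge.length == pytest.approx(14.0)

    def test_synthetic_event_tree_depths(self):
        # one speciation at 100 Ma in a 150 Ma run -> two tips, depth 100
        from paleogradient.ecoevo import species as sp

        g = GridSpec(20.0, 20.0)
        rec = SimulationRecord(
            grid=g, ages=np.arange(150, -1, -1, dtype=float),
            scenario_id="M0", seed=0,
            richness=np.zeros((151,) + g.shape, dtype=np.int32),
        )
        a = sp.Species(sid=1, parent=None, origin_age=150.0, origin_step=0)
        b = sp.Species(sid=2, parent=1, origin_age=100.0, origin_step=50)
        a.n[0] = b.n[1] = 0.5
        rec.species = {1: a, 2: b}
        rec.events = [
            Event(0, 150.0, "origination", 1, None, (0,)),
            Event(50, 100.0, "origination", 2, 1, (1,)),
        ]
        nwk = write_phylogeny(rec)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 2
        for leaf in tree.leaf_nodes():
            assert leaf.edge.length == pytest.approx(100.0)

    def test_round_trip_recovers_branching_times(self, tiny_world):
        rec = None
        for i, draw in enumerate(sample_parameters(6, seed=1)):
            rec = run_simulation(tiny_world, SCENARIOS["M1e"], draw, seed=5 + i)
            if len(rec.species) >= 2:
                break
        assert len(rec.species) >= 2, "no draw produced speciation"
        nwk = write_phylogeny(rec)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tips = {leaf.taxon.label for leaf in tree.leaf_nodes()}
        assert len(tips) == len(rec.species)
        orig = sum(1 for e in rec.events if e.kind == "origination")
        assert len(tips) == orig
        extant = {f"s{s.sid} extant" for s in rec.species.values() if s.extant}
        assert extant <= tips
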