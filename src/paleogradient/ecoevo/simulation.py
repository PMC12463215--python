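"""The forward simulation loop and its outputs.

Per step order: landscape update -> dispersal -> geographic clustering
-> divergence & speciation -> trait evolution -> ecology (suitability,
carrying capacity, logistic update, local and global extinction). All
randomness flows through one numpy Generator per simulation, so runs
are bit-reproducible for a fixed seed.

Kernel and reachability length scales are anchored to a 2° grid (the
scale on which the Weibull dispersal parameters are defined); on other
resolutions effective distances rescale by lat_res / 2° so connectivity
is resolution-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grid import GridSpec
from ..physiography import compute_physiography
from ..world import LandscapeSeries
from . import species as sp
from .ecology import MIN_ABUNDANCE, carrying_capacity, reapportion, suitability
from .graph import CostGraph, barrier_mask, partition_clusters
from .scenarios import ParamDraw, Scenario, TEMPERATURE_SCALE

REFERENCE_RES_DEG = 2.0
DEFAULT_SPINUP_STEPS = 25


@dataclass(frozen=True)
class Event:
    step: int
    age: float
    kind: str  # "origination" | "extinction"
    sid: int
    parent: int | None
    cells: tuple[int, ...]  # flat grid indices (founding cluster / last cells)


@dataclass
class SimulationRecord:
    """Everything a run produces: per-step richness grids, the event
    ledger, the species table and enough to write the phylogeny."""

    grid: GridSpec
    ages: np.ndarray
    scenario_id: str
    seed: int
    richness: np.ndarray  # (n_steps, nlat, nlon) int32
    events: list[Event] = field(default_factory=list)
    species: dict[int, sp.Species] = field(default_factory=dict)
    extant_counts: np.ndarray | None = None
    spinup_steps: int = DEFAULT_SPINUP_STEPS

    @property
    def n_steps(self) -> int:
        return self.ages.size

    def event_table(self) -> pd.DataFrame:
        rows = [
            {
                "step": e.step,
                "age": e.age,
                "event": e.kind,
                "species": e.sid,
                "parent": e.parent if e.parent is not None else -1,
                "n_cells": len(e.cells),
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=["step", "age", "event", "species", "parent", "n_cells"],
        )

    def counts_per_step(self, kind: str) -> np.ndarray:
        out = np.zeros(self.n_steps, dtype=np.int64)
        for e in self.events:
            if e.kind == kind:
                out[e.step] += 1
        return out

    def check_bookkeeping(self) -> None:
        """S(t+1) = S(t) + originations - extinctions, at every step."""
        orig = self.counts_per_step("origination")
        ext = self.counts_per_step("extinction")
        s = np.cumsum(orig - ext)
        if self.extant_counts is None or not np.array_equal(s, self.extant_counts):
            raise RuntimeError("species bookkeeping violated")


class InitializationError(ValueError):
    pass


def _default_seed_cell(land: np.ndarray, grid: GridSpec) -> int:
    """Cell of the largest contiguous landmass nearest the equator."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    from ..grid import NEIGHBOR_OFFSETS

    nlat, nlon = land.shape
    idx = np.arange(nlat * nlon).reshape(nlat, nlon)
    a_list, b_list = [], []
    for dr, dc in NEIGHBOR_OFFSETS:
        src_r, src_c = np.nonzero(land)
        dst_r = src_r + dr
        ok = (dst_r >= 0) & (dst_r < nlat)
        src_r, src_c, dst_r = src_r[ok], src_c[ok], dst_r[ok]
        dst_c = (src_c + dc) % nlon
        keep = land[dst_r, dst_c]
        a_list.append(idx[src_r[keep], src_c[keep]])
        b_list.append(idx[dst_r[keep], dst_c[keep]])
    land_flat = np.flatnonzero(land.ravel())
    pos = {int(f): i for i, f in enumerate(land_flat)}
    a = np.array([pos[int(x)] for x in np.concatenate(a_list)], dtype=np.int64)
    b = np.array([pos[int(x)] for x in np.concatenate(b_list)], dtype=np.int64)
    m = coo_matrix(
        (np.ones(a.size), (a, b)), shape=(land_flat.size, land_flat.size)
    )
    _, labels = connected_components(m, directed=False)
    largest = np.argmax(np.bincount(labels))
    members = land_flat[labels == largest]
    lats = np.abs(grid.lat_grid().ravel()[members])
    order = np.lexsort((members, lats))
    return int(members[order[0]])


def run_simulation(
    series: LandscapeSeries,
    scenario: Scenario,
    draw: ParamDraw,
    seed: int,
    init: list[tuple[int, int]] | None = None,
    spinup_steps: int = DEFAULT_SPINUP_STEPS,
) -> SimulationRecord:
    """Run one forward simulation over the full landscape series.

    Parameters
    ----------
    init : optional list of (row, col) seed cells for ancestral species
        (one species per cell). Defaults to a single ancestor on the
        largest landmass cell nearest the equator at the first step.
    """
    grid = series.grid
    nlat, nlon = grid.shape
    rng = np.random.default_rng(seed)
    lat_flat = grid.lat_grid().ravel()
    scale_factor = grid.lat_res / REFERENCE_RES_DEG
    p_max_series = float(np.nanmax(series.ds["precipitation"].values))
    if p_max_series <= 0:
        raise InitializationError("precipitation must be positive somewhere")

    ages = series.times
    record = SimulationRecord(
        grid=grid,
        ages=ages,
        scenario_id=scenario.id,
        seed=seed,
        richness=np.zeros((ages.size, nlat, nlon), dtype=np.int32),
        spinup_steps=spinup_steps,
    )
    extant_counts = np.zeros(ages.size, dtype=np.int64)

    # --- initialization on the first slice ---------------------------
    sl = series.slice(0)
    land = sl["land"]
    if init is None:
        seed_cells = [_default_seed_cell(land, grid)]
    else:
        seed_cells = [int(r) * nlon + int(c) for r, c in init]
        for f in seed_cells:
            if not land.ravel()[f]:
                raise InitializationError(
                    f"ancestral placement on sea cell (flat index {f})"
                )
    all_species: dict[int, sp.Species] = {}
    next_sid = 1
    t_norm = sl["temperature"].ravel() / TEMPERATURE_SCALE
    p_norm = sl["precipitation"].ravel() / p_max_series
    for f in seed_cells:
        s = sp.Species(sid=next_sid, parent=None, origin_age=float(ages[0]),
                       origin_step=0)
        s.n[f] = MIN_ABUNDANCE
        s.t_opt[f] = float(t_norm[f])
        s.p_opt[f] = float(p_norm[f])
        s.deme[f] = 0
        all_species[next_sid] = s
        record.events.append(
            Event(0, float(ages[0]), "origination", next_sid, None, (f,))
        )
        next_sid += 1

    # step 0: run the ecology phase so abundances are consistent
    ks_grid = _ks_grid(sl, grid, scenario, p_max_series)
    _ecology_phase(all_species, ks_grid, t_norm, p_norm, draw, force_all=True)
    for s in _extant(all_species):
        if not s.n:
            _mark_extinct(record, s, 0, float(ages[0]), s.last_cells)
    _record_step(record, all_species, 0, extant_counts)

    # --- main loop ----------------------------------------------------
    for k in range(1, ages.size):
        age = float(ages[k])
        sl = series.slice(k)
        land = sl["land"]
        land_flat_mask = land.ravel()
        t_norm = sl["temperature"].ravel() / TEMPERATURE_SCALE
        p_norm = sl["precipitation"].ravel() / p_max_series

        phys = None
        if scenario.uses_phi:
            phys = compute_physiography(
                sl["elevation"], sl["discharge"], land, grid
            )
        phi_grid = phys.phi if phys is not None else None

        # 1. landscape update: drop populations whose cell drowned
        for s in _extant(all_species):
            lost = [c for c in s.cells() if not land_flat_mask[c]]
            last = tuple(s.cells())
            for c in lost:
                s.remove_cell(c)
            if lost and not s.n:
                _mark_extinct(record, s, k, age, last)

        graph = CostGraph(
            land, grid,
            phi=phi_grid if scenario.dispersal_mode == "distance_phi" else None,
            dispersal_mode=scenario.dispersal_mode,
        )
        # speciation clustering runs on plain geographic distance unless
        # the scenario severs edges at physiographic barriers (M1s); in
        # particular distance+phi dispersal (M1d) must not leak into it
        spec_graph = None
        if scenario.speciation_mode == "phi":
            bar = barrier_mask(phi_grid, land, scenario.barrier_quantile)
            spec_graph = CostGraph(land, grid, barrier=bar)
        elif scenario.dispersal_mode == "distance_phi":
            spec_graph = CostGraph(land, grid)

        reach_km = draw.scale * scale_factor
        ks_grid = _ks_grid(sl, grid, scenario, p_max_series, phys)

        # 2. dispersal
        for s in _extant(all_species):
            _disperse(s, graph, draw, scale_factor, rng, land_flat_mask)

        # 3-5. clustering, divergence/speciation, trait evolution
        new_species: list[sp.Species] = []
        for s in _extant(all_species):
            cells = s.cells()
            if not cells:
                continue
            labels_arr = partition_clusters(
                np.array(cells), graph, reach_km, speciation_graph=spec_graph
            )
            labels = {c: int(l) for c, l in zip(cells, labels_arr)}
            sp.refine_demes(s, labels)
            sp.update_divergence(s, labels)
            for lab in sp.speciating_clusters(s, labels, draw.tau):
                child = sp.bud_species(s, labels, lab, next_sid, age, k)
                new_species.append(child)
                record.events.append(
                    Event(k, age, "origination", child.sid, s.sid,
                          tuple(child.cells()))
                )
                next_sid += 1
            # re-evaluate labels for trait evolution on remaining cells
            remaining = s.cells()
            labels = {c: labels[c] for c in remaining}
            t_site = {c: float(t_norm[c]) for c in remaining}
            sp.evolve_traits(s, labels, t_site, draw.sigma, rng)
        for child in new_species:
            cells = child.cells()
            labels = {c: 0 for c in cells}
            t_site = {c: float(t_norm[c]) for c in cells}
            sp.evolve_traits(child, labels, t_site, draw.sigma, rng)
            all_species[child.sid] = child

        # 6. ecology
        _ecology_phase(all_species, ks_grid, t_norm, p_norm, draw)
        for s in _extant(all_species):
            if not s.n:
                # last cells were wiped in the ecology phase
                _mark_extinct(record, s, k, age, s.last_cells)

        _record_step(record, all_species, k, extant_counts)

    record.extant_counts = extant_counts
    record.species = all_species
    record.check_bookkeeping()
    return record


def _extant(all_species: dict[int, sp.Species]) -> list[sp.Species]:
    return [s for _, s in sorted(all_species.items()) if s.extant]


def _mark_extinct(record, s: sp.Species, step: int, age: float, last_cells) -> None:
    s.extinct_age = age
    s.extinct_step = step
    record.events.append(
        Event(step, age, "extinction", s.sid, s.parent, tuple(last_cells))
    )


def _record_step(record, all_species, k, extant_counts) -> None:
    nlat, nlon = record.grid.shape
    rich = np.zeros(nlat * nlon, dtype=np.int32)
    count = 0
    for s in all_species.values():
        if s.extant:
            count += 1
            for c in s.n:
                rich[c] += 1
    record.richness[k] = rich.reshape(nlat, nlon)
    extant_counts[k] = count


def _ks_grid(sl, grid, scenario, p_max_series, phys=None) -> np.ndarray:
    """Per-cell carrying capacity for one slice (flat, NaN on sea)."""
    land = sl["land"]
    p = sl["precipitation"]
    p_max = np.nanmax(np.where(land, p, np.nan))
    p_bar = np.where(land, p / max(p_max, 1e-12), np.nan)
    from ..physiography import hydro_categories

    disc = np.where(land, np.nan_to_num(sl["discharge"], nan=0.0), np.nan)
    h = hydro_categories(np.where(land, disc, np.nan)).astype(float)
    h[~land] = np.nan
    h_max = np.nanmax(h)
    h_bar = h / max(h_max, 1.0)
    if scenario.gamma > 0:
        if phys is None:
            phys = compute_physiography(
                sl["elevation"], sl["discharge"], land, grid
            )
        phi = phys.phi
        phi_max = np.nanmax(np.where(land, phi, np.nan))
        phi_bar = phi / max(phi_max, 1e-12) if np.isfinite(phi_max) else phi
    else:
        phi_bar = np.zeros_like(p_bar)
    ks = carrying_capacity(p_bar, h_bar, phi_bar, grid.lat_grid(), scenario)
    ks = np.where(land, ks, np.nan)
    return ks.ravel()


def _disperse(
    s: sp.Species,
    graph: CostGraph,
    draw: ParamDraw,
    scale_factor: float,
    rng: np.random.Generator,
    land_flat_mask: np.ndarray,
) -> None:
    """One Weibull kernel draw per occupied cell; every land cell within
    that cost-distance becomes a candidate colonization. Arrivals copy
    the trait values and deme of their (cost-)nearest source."""
    cells = s.cells()
    if not cells:
        return
    radii = draw.scale * scale_factor * rng.weibull(draw.shape, size=len(cells))
    land_cells = graph.land_idx
    best_src: dict[int, tuple[float, int]] = {}
    occupied = set(cells)
    for c, r in zip(cells, radii):
        row = graph.dist[graph.position(c)]
        within = land_cells[row <= r]
        for tgt, dist in zip(within, row[row <= r]):
            tgt = int(tgt)
            if tgt in occupied:
                continue
            cur = best_src.get(tgt)
            if cur is None or (dist, c) < cur:
                best_src[tgt] = (float(dist), c)
    for tgt, (_, src) in sorted(best_src.items()):
        s.n[tgt] = MIN_ABUNDANCE
        s.t_opt[tgt] = s.t_opt[src]
        s.p_opt[tgt] = s.p_opt[src]
        s.deme[tgt] = s.deme[src]
        s.arrivals.add(tgt)


def _ecology_phase(all_species, ks_flat, t_norm, p_norm, draw, force_all=False):
    """Per-cell suitability, reapportionment on colonization / local
    extinction, logistic growth otherwise; then global extinction."""
    occupants: dict[int, list[sp.Species]] = {}
    for s in _extant(all_species):
        s.last_cells = tuple(s.cells())
        for c in s.n:
            occupants.setdefault(c, []).append(s)
    for c in sorted(occupants):
        members = occupants[c]
        ks = ks_flat[c]
        if not np.isfinite(ks):
            ks = 0.0
        k_vals = np.array([
            suitability(m.t_opt[c], m.p_opt[c], t_norm[c], p_norm[c],
                        ks, draw.omega_t, draw.omega_p)
            for m in members
        ])
        has_arrival = force_all or any(c in m.arrivals for m in members)
        if has_arrival:
            shares = reapportion(k_vals, ks)
        else:
            n_vals = np.array([m.n[c] for m in members])
            n_new = n_vals + n_vals * (k_vals - n_vals)
            dropped = n_new < MIN_ABUNDANCE
            if dropped.any():
                keep_k = np.where(dropped, 0.0, k_vals)
                shares = reapportion(keep_k, ks)
            else:
                shares = n_new
        for m, val in zip(members, shares):
            if val >= MIN_ABUNDANCE:
                m.n[c] = float(val)
            else:
                m.remove_cell(c)
    for s in _extant(all_species):
        s.arrivals.clear()


def write_phylogeny(record: SimulationRecord) -> str:
    """Newick string for the run's complete phylogeny (budding model).

    Branch lengths are in Myr. Tip labels are ``s<id>`` with an
    ``extant``/``extinct`` suffix; every species (including extinct
    ones) is a tip, and internal node times are the speciation ages.
    """
    if not record.species:
        raise ValueError("record has no species")
    children: dict[int, list[tuple[float, int]]] = {}
    for e in record.events:
        if e.kind == "origination" and e.parent is not None:
            children.setdefault(e.parent, []).append((e.age, e.sid))
    for v in children.values():
        v.sort(key=lambda t: (-t[0], t[1]))  # earliest (largest age) first

    def end_age(sid: int) -> float:
        s = record.species[sid]
        return s.extinct_age if s.extinct_age is not None else float(record.ages[-1])

    def tip_label(sid: int) -> str:
        s = record.species[sid]
        return f"s{sid}_{'extant' if s.extant else 'extinct'}"

    def subtree(sid: int, from_age: float, evs: list[tuple[float, int]]) -> str:
        if not evs:
            return f"{tip_label(sid)}:{from_age - end_age(sid):.6f}"
        a, child = evs[0]
        left = subtree(sid, a, evs[1:])
        right = subtree(child, a, list(children.get(child, [])))
        return f"({left},{right}):{from_age - a:.6f}"

    roots = [s for s in record.species.values() if s.parent is None]
    parts = [
        subtree(r.sid, r.origin_age, list(children.get(r.sid, [])))
        for r in sorted(roots, key=lambda s: s.sid)
    ]
    if len(parts) == 1:
        p = parts[0]
        return p + ";" if p.startswith("(") else f"({p});"
    return "(" + ",".join(parts) + ");"
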