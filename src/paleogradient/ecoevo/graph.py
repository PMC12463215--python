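"""Dispersal cost graphs and geographic clustering.

Cells are graph nodes connected to their 8-neighbours (longitude wraps,
latitude clamps). Edge weight is the great-circle distance between cell
centers in km; any edge touching a sea cell costs double (water
crossing); under distance+Φ dispersal, land–land edges are further
multiplied by (1 + |ΔΦ|) so environmentally dissimilar terrain is
harder to traverse. Pairwise cost-distance is the shortest path.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from ..grid import GridSpec, NEIGHBOR_OFFSETS, great_circle_km


class CostGraph:
    """Weighted 8-neighbour graph over one landscape slice.

    Attributes
    ----------
    land_idx : flat indices (row-major) of land cells.
    dist : (n_land, n_land) cost-distance matrix (km), shortest paths;
        sea cells may be traversed at doubled cost.
    """

    def __init__(
        self,
        land: np.ndarray,
        grid: GridSpec,
        phi: np.ndarray | None = None,
        dispersal_mode: str = "distance",
        barrier: np.ndarray | None = None,
    ):
        self.grid = grid
        self.land = np.asarray(land, dtype=bool)
        nlat, nlon = self.land.shape
        self.land_idx = np.flatnonzero(self.land.ravel())
        self._pos = {int(f): i for i, f in enumerate(self.land_idx)}

        lat_g, lon_g = grid.lat_grid().ravel(), grid.lon_grid().ravel()
        rows_src, cols_dst, weights = [], [], []
        sea = ~self.land.ravel()
        use_phi = dispersal_mode == "distance_phi" and phi is not None
        phi_flat = None
        if use_phi:
            phi_flat = np.nan_to_num(np.asarray(phi, dtype=float).ravel(), nan=0.0)
        r_idx = np.arange(nlat * nlon).reshape(nlat, nlon)
        for dr, dc in NEIGHBOR_OFFSETS:
            src_r, src_c = np.nonzero(np.ones((nlat, nlon), dtype=bool))
            dst_r = src_r + dr
            ok = (dst_r >= 0) & (dst_r < nlat)
            src_r, src_c, dst_r = src_r[ok], src_c[ok], dst_r[ok]
            dst_c = (src_c + dc) % nlon
            a = r_idx[src_r, src_c]
            b = r_idx[dst_r, dst_c]
            d = great_circle_km(lat_g[a], lon_g[a], lat_g[b], lon_g[b])
            w = d.copy()
            touches_sea = sea[a] | sea[b]
            w[touches_sea] *= 2.0
            if use_phi:
                both_land = ~touches_sea
                w[both_land] *= 1.0 + np.abs(
                    phi_flat[a[both_land]] - phi_flat[b[both_land]]
                )
            rows_src.append(a)
            cols_dst.append(b)
            weights.append(w)
        a = np.concatenate(rows_src)
        b = np.concatenate(cols_dst)
        w = np.concatenate(weights)
        if barrier is not None:
            bar = np.asarray(barrier, dtype=bool).ravel()
            keep = ~(bar[a] | bar[b])
            a, b, w = a[keep], b[keep], w[keep]
        n = nlat * nlon
        self.adjacency = coo_matrix((w, (a, b)), shape=(n, n)).tocsr()
        # direct land-land contacts present in this graph (populations in
        # bordering cells are never allopatric, whatever the kernel scale)
        ll = ~(sea[a] | sea[b])
        self.land_contacts = coo_matrix(
            (np.ones(ll.sum(), dtype=np.int8), (a[ll], b[ll])), shape=(n, n)
        ).tocsr()
        self._dist: np.ndarray | None = None

    @property
    def dist(self) -> np.ndarray:
        """All-pairs land-to-land cost-distance (km), lazily computed."""
        if self._dist is None:
            full = dijkstra(self.adjacency, directed=False,
                            indices=self.land_idx)
            self._dist = full[:, self.land_idx]
        return self._dist

    def position(self, flat_index: int) -> int:
        """Row of a land cell (flat grid index) in the dist matrix."""
        return self._pos[int(flat_index)]


def dispersal_cost_graph(
    land: np.ndarray,
    grid: GridSpec,
    phi: np.ndarray | None,
    scenario,
) -> CostGraph:
    """Build the scenario's dispersal graph for one slice. Φ enters the
    edge weights only in distance+Φ mode (M1d)."""
    mode = scenario.dispersal_mode if scenario is not None else "distance"
    return CostGraph(land, grid, phi=phi if mode == "distance_phi" else None,
                     dispersal_mode=mode)


def barrier_mask(phi: np.ndarray, land: np.ndarray, quantile: float) -> np.ndarray:
    """Land cells whose Φ exceeds the given quantile of the land-Φ
    distribution (physiographic barriers for Φ-based speciation)."""
    phi = np.asarray(phi, dtype=float)
    vals = phi[np.asarray(land, dtype=bool) & np.isfinite(phi)]
    if vals.size == 0:
        return np.zeros(phi.shape, dtype=bool)
    thr = np.quantile(vals, quantile)
    out = np.zeros(phi.shape, dtype=bool)
    out[np.asarray(land, dtype=bool)] = np.nan_to_num(
        phi[np.asarray(land, dtype=bool)], nan=-np.inf) > thr
    return out


def partition_clusters(
    occupied: np.ndarray,
    graph: CostGraph,
    reach_km: float,
    speciation_graph: CostGraph | None = None,
) -> np.ndarray:
    """Connected components of a species' occupied cells.

    Two occupied cells connect when their cost-distance is at most
    `reach_km` (the dispersal kernel scale serves as the reachability
    proxy — the model's only length scale). Under Φ-based speciation a
    severed graph (edges through barrier cells removed) supplies the
    distances instead, so physiographic barriers isolate populations
    that plain distance would connect.

    Parameters
    ----------
    occupied : flat grid indices of the species' occupied cells.
    Returns labels (0..k-1) aligned with `occupied`.
    """
    occupied = np.asarray(occupied, dtype=np.int64)
    if occupied.size == 0:
        return np.zeros(0, dtype=np.int64)
    g = speciation_graph if speciation_graph is not None else graph
    pos = np.array([g.position(f) for f in occupied])
    sub = g.dist[np.ix_(pos, pos)]
    adj = (sub <= reach_km).astype(np.int8)
    n_comp, labels = connected_components(coo_matrix(adj), directed=False)
    return labels.astype(np.int64)
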