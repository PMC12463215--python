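"""Independent brute-force reference implementations used as oracles."""

import numpy as np


def brute_force_tpi(elev, band, land):
    """Per-cell double loop TPI (lon wrap, lat clamp), independent of the
    vectorized implementation."""
    nlat, nlon = elev.shape
    out = np.full(elev.shape, np.nan)
    for i in range(nlat):
        for j in range(nlon):
            if not land[i, j]:
                continue
            vals = []
            for di in range(-band.outer, band.outer + 1):
                for dj in range(-band.outer, band.outer + 1):
                    r = max(abs(di), abs(dj))
                    if not (band.inner < r <= band.outer):
                        continue
                    ni, nj = i + di, (j + dj) % nlon
                    if 0 <= ni < nlat and land[ni, nj]:
                        vals.append(elev[ni, nj])
            if vals:
                out[i, j] = elev[i, j] - np.mean(vals)
    return out


def brute_force_components(occupied, dist, reach):
    """Union-find over the thresholded pairwise distance matrix."""
    n = len(occupied)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= reach:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return [relabel[r] for r in roots]
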