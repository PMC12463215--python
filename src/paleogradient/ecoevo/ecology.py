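"""Site-level ecology: suitability, carrying capacity, population
dynamics and abundance reapportionment.

All quantities are in normalized units: temperature divided by 100 °C,
precipitation by its series maximum, and abundances bounded by the
site's carrying capacity Ks <= Kmax = 1. Local populations below 0.01
are removed (local extinction).
"""

from __future__ import annotations

import numpy as np

MIN_ABUNDANCE = 0.01


def suitability(t_opt, p_opt, t_site, p_site, ks, omega_t, omega_p):
    """Gaussian environmental suitability.

    K = Ks * exp(-((T̄i - T̄s)/ωt)^2) * exp(-((P̄i - P̄s)/ωp)^2),
    strictly decreasing in each niche mismatch; equals Ks at the optimum.
    """
    dt = (np.asarray(t_opt) - t_site) / omega_t
    dp = (np.asarray(p_opt) - p_site) / omega_p
    return ks * np.exp(-(dt**2)) * np.exp(-(dp**2))


def carrying_capacity(p_bar, h_bar, phi_bar, lat, scenario, kmax: float = 1.0):
    """Ks = min(Kmax, (α·P̄ + β·H̄ + γ·Φ̄)·Kmax) · cos(lat).

    Inputs P̄, H̄, Φ̄ are each normalized by their maximum over the
    slice; cos(lat) scales for cell area. |lat| >= 90 gives 0. Φ̄ is only
    consulted when γ > 0 so scenarios without a physiography term are
    insensitive to (even invalid) Φ values.
    """
    p_bar = np.asarray(p_bar, dtype=float)
    resources = scenario.alpha * p_bar + scenario.beta * np.asarray(h_bar, dtype=float)
    if scenario.gamma > 0:
        resources = resources + scenario.gamma * np.nan_to_num(
            np.asarray(phi_bar, dtype=float), nan=0.0
        )
    lat = np.asarray(lat, dtype=float)
    coslat = np.where(np.abs(lat) >= 90, 0.0, np.cos(np.deg2rad(lat)))
    return np.minimum(kmax, resources * kmax) * coslat


def population_step(n, k):
    """Discrete logistic update dN = N·(K − N): N' = N + N·(K − N).

    Populations below MIN_ABUNDANCE after the update are set to 0
    (locally extinct). For N0 in (0, K], K <= 1, the map converges
    monotonically to K.
    """
    n = np.asarray(n, dtype=float)
    out = n + n * (np.asarray(k, dtype=float) - n)
    return np.where(out < MIN_ABUNDANCE, 0.0, out)


def reapportion(suitabilities, ks: float):
    """Split the site's total abundance (set to Ks) across the present
    species proportionally to their suitability K; shares below
    MIN_ABUNDANCE fail to establish. All suitabilities zero empties the
    site. Removal of a sub-threshold share re-triggers the split among
    the survivors until stable.
    """
    k = np.asarray(suitabilities, dtype=float)
    shares = np.zeros_like(k)
    alive = k > 0
    while alive.any():
        total = k[alive].sum()
        cand = np.zeros_like(k)
        cand[alive] = ks * k[alive] / total
        drop = alive & (cand < MIN_ABUNDANCE)
        if not drop.any():
            shares[:] = 0.0
            shares[alive] = cand[alive]
            return shares
        alive &= ~drop
    return np.zeros_like(k)
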