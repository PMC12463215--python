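"""Quantifying LDG shape and climate belts.

The latitudinal richness profile of each hemisphere at each time slice
is collapsed onto a hyperbolic tangent

    α(lat) = αmin + Δα · tanh(θ · (lat − lat0))

on absolute latitude, fitted by bounded least squares with multiple
starts. The reported shape descriptors are the raw slope θ, the maximum
gradient |θ·Δα| (the curve's steepest descent), the transition midpoint
lat0, and the transition width 2/|θ|. Fits are canonicalized to θ >= 0
(the (Δα, θ) → (−Δα, −θ) reflection leaves the curve unchanged).

Simplified Köppen belts are classified from mean annual temperature
(MAT, °C) and precipitation (MAP, m/yr) in precedence order
A → B → C → D → E → none; the arid rule compares MAP in cm/yr against
the critical threshold κ = 2·MAT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

KOPPEN_CLASSES = ("A", "B", "C", "D", "E", "none")
_PRECEDENCE = {c: i for i, c in enumerate(KOPPEN_CLASSES)}


@dataclass
class LDGFit:
    """Result of one hemisphere/time tanh fit."""

    hemisphere: str  # "N" | "S"
    time: float  # Ma
    alpha_min: float
    delta_alpha: float
    theta: float  # per degree latitude (canonical theta >= 0)
    lat0: float  # transition midpoint, degrees absolute latitude
    residual_norm: float
    converged: bool

    @property
    def max_gradient(self) -> float:
        """Steepest slope of the fitted curve, |θ·Δα|."""
        return abs(self.theta * self.delta_alpha)

    @property
    def width(self) -> float:
        """Transition width 2/|θ| (degrees); inf for a flat fit."""
        return 2.0 / abs(self.theta) if self.theta != 0 else np.inf

    def predict(self, lat_abs: np.ndarray) -> np.ndarray:
        return self.alpha_min + self.delta_alpha * np.tanh(
            self.theta * (np.asarray(lat_abs, dtype=float) - self.lat0)
        )


def _model(params, x):
    a0, da, th, l0 = params
    return a0 + da * np.tanh(th * (x - l0))


def fit_tanh(
    lat_abs: np.ndarray,
    profile: np.ndarray,
    hemisphere: str = "N",
    time: float = 0.0,
) -> LDGFit:
    """Least-squares tanh fit of a richness-vs-|latitude| profile.

    Requires at least 8 bands with data. A (near-)flat profile returns
    converged=False with degenerate parameters (θ=0) rather than a
    spurious slope. Four starts are tried: both θ signs crossed with the
    two lat0 quartiles of the latitude span.
    """
    x = np.asarray(lat_abs, dtype=float)
    y = np.asarray(profile, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 8:
        raise ValueError("need at least 8 latitude bands with data")
    scale = max(np.ptp(y), 1e-30)
    if np.ptp(y) < 1e-10 * max(1.0, np.abs(y).max()):
        return LDGFit(hemisphere, time, float(y.mean()), 0.0, 0.0,
                      float(np.median(x)), 0.0, converged=False)

    lo = [y.min() - 2 * scale, -4 * scale, -5.0, x.min()]
    hi = [y.max() + 2 * scale, 4 * scale, 5.0, x.max()]
    q1, q3 = np.quantile(x, [0.25, 0.75])
    starts = [
        (y.min(), (y.max() - y.min()) / 2, th0, l00)
        for th0 in (0.1, -0.1)
        for l00 in (q1, q3)
    ]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(
                lambda p: _model(p, x) - y, p0, bounds=(lo, hi),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return LDGFit(hemisphere, time, float(y.mean()), 0.0, 0.0,
                      float(np.median(x)), np.inf, converged=False)
    a0, da, th, l0 = best.x
    if th < 0:  # canonical form
        th, da = -th, -da
    resid = float(np.sqrt(2 * best.cost))
    return LDGFit(hemisphere, time, float(a0), float(da), float(th),
                  float(l0), resid, converged=True)


def fit_hemispheres(
    lats: np.ndarray, profile: np.ndarray, time: float = 0.0
) -> dict[str, LDGFit]:
    """Fit each hemisphere of a signed-latitude profile separately."""
    lats = np.asarray(lats, dtype=float)
    profile = np.asarray(profile, dtype=float)
    out = {}
    for hemi, mask in (("N", lats >= 0), ("S", lats <= 0)):
        out[hemi] = fit_tanh(np.abs(lats[mask]), profile[mask], hemi, time)
    return out


# ---------------------------------------------------------------------
# Köppen belts
# ---------------------------------------------------------------------

def koppen_classify(mat: np.ndarray, map_myr: np.ndarray) -> np.ndarray:
    """Simplified Köppen class per cell from MAT (°C) and MAP (m/yr).

    Precedence A → B → C → D → E → none:
      A: MAT > 18 and MAP > 0.6 m/yr
      B: MAP (cm/yr) < κ = 2·MAT
      C: 5 < MAT < 18 and 0.5 < MAP < 2
      D: −5 < MAT < 10 and 0.4 < MAP < 1
      E: MAT < 10
    Total on finite MAT and MAP >= 0; MAP is accepted in m/yr (the cm
    conversion is internal to the arid rule).
    """
    mat = np.asarray(mat, dtype=float)
    map_m = np.asarray(map_myr, dtype=float)
    map_cm = map_m * 100.0
    out = np.full(mat.shape, "none", dtype="<U4")
    rule_e = mat < 10
    rule_d = (-5 < mat) & (mat < 10) & (0.4 < map_m) & (map_m < 1)
    rule_c = (5 < mat) & (mat < 18) & (0.5 < map_m) & (map_m < 2)
    rule_b = map_cm < 2.0 * mat
    rule_a = (mat > 18) & (map_m > 0.6)
    out[rule_e] = "E"
    out[rule_d] = "D"
    out[rule_c] = "C"
    out[rule_b] = "B"
    out[rule_a] = "A"
    return out


def belt_profile(
    classes: np.ndarray, land: np.ndarray
) -> np.ndarray:
    """Modal Köppen class per latitude band per step, land cells only.

    `classes` is (n_steps, nlat, nlon) of class strings; ties go to the
    lower-precedence letter (A < B < C < D < E < none). Empty bands are
    "none".
    """
    classes = np.asarray(classes)
    land = np.asarray(land, dtype=bool)
    n_steps, nlat, _ = classes.shape
    out = np.full((n_steps, nlat), "none", dtype="<U4")
    for t in range(n_steps):
        for i in range(nlat):
            vals = classes[t, i, :][land[t, i, :]]
            if vals.size == 0:
                continue
            uniq, cnt = np.unique(vals, return_counts=True)
            best = max(
                zip(uniq, cnt), key=lambda uc: (uc[1], -_PRECEDENCE[uc[0]])
            )
            out[t, i] = best[0]
    return out


def koppen_series(series) -> np.ndarray:
    """Classify every slice of a landscape series (all cells)."""
    t = series.ds["temperature"].values
    p = series.ds["precipitation"].values
    return koppen_classify(t, p)
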