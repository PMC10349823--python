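"""Surface-to-volume ratio (SVR) geometry: two spheres and one cone.

A bird's body is idealised as a head sphere, a torso sphere, and a conical
bill whose base radius is proportional to its height (r_b = k · h).  Total
surface and volume are simple sums of the primitive surfaces and volumes —
sphere–sphere and sphere–cone overlaps are deliberately ignored, since the
model's purpose is the qualitative scaling argument, not anatomy: shrinking
the body raises SVR (Bergmann's logic), growing the bill raises SVR (Allen's
logic), and small joint changes in both can match the SVR gain of a large
change in either one alone (complementarity).

All lengths are in arbitrary units; SVR has units of 1/length and is exactly
scale-inverse (all lengths × s ⇒ SVR / s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr

__all__ = [
    "BodyGeometry",
    "SvrSummary",
    "DEFAULT_GEOMETRY",
    "sphere_svr",
    "composite_svr",
    "shrink_body",
    "grow_beak",
    "compensating_beak_increase",
    "complementarity_curve",
    "proxy_simulation",
    "proxy_correlations",
]


@dataclass(frozen=True)
class BodyGeometry:
    """Two sphere radii plus a cone of height ``h_bill`` and base radius k·h."""

    r_head: float = 1.0
    r_torso: float = 2.0
    h_bill: float = 1.0
    k_bill: float = 0.3

    def __post_init__(self) -> None:
        if min(self.r_head, self.r_torso, self.h_bill, self.k_bill) <= 0:
            raise ValueError("all geometry dimensions must be positive")

    @property
    def r_base(self) -> float:
        return self.k_bill * self.h_bill


@dataclass(frozen=True)
class SvrSummary:
    surface: float
    volume: float
    svr: float


DEFAULT_GEOMETRY = BodyGeometry()


def sphere_svr(r: float) -> float:
    """SVR of a sphere: 4πr² / (4/3 πr³) = 3/r."""
    if r <= 0:
        raise ValueError("radius must be positive")
    return 3.0 / r


def _cone_surface(h: float, r: float) -> float:
    slant = np.hypot(h, r)
    return np.pi * r * (r + slant)  # lateral + base


def _cone_volume(h: float, r: float) -> float:
    return np.pi * r**2 * h / 3.0


def composite_svr(g: BodyGeometry) -> SvrSummary:
    """Total surface, volume, and SVR of the two-spheres-one-cone body."""
    surface = (
        4 * np.pi * g.r_head**2
        + 4 * np.pi * g.r_torso**2
        + _cone_surface(g.h_bill, g.r_base)
    )
    volume = (
        4 / 3 * np.pi * g.r_head**3
        + 4 / 3 * np.pi * g.r_torso**3
        + _cone_volume(g.h_bill, g.r_base)
    )
    return SvrSummary(surface=surface, volume=volume, svr=surface / volume)


def shrink_body(g: BodyGeometry, f: float) -> BodyGeometry:
    """Reduce combined sphere volume by exactly fraction ``f``; cone unchanged.

    Both radii scale by (1 − f)^(1/3), so each sphere's volume (and hence the
    sum) drops by exactly f.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("body reduction fraction must be in [0, 1)")
    s = (1.0 - f) ** (1.0 / 3.0)
    return replace(g, r_head=g.r_head * s, r_torso=g.r_torso * s)


def grow_beak(g: BodyGeometry, gfrac: float) -> BodyGeometry:
    """Increase cone volume by exactly fraction ``gfrac`` (isometric); spheres unchanged."""
    if gfrac < 0:
        raise ValueError("beak growth fraction must be nonnegative")
    s = (1.0 + gfrac) ** (1.0 / 3.0)
    return replace(g, h_bill=g.h_bill * s)


def compensating_beak_increase(
    g: BodyGeometry, target_delta_svr: float, max_gfrac: float = 10.0
) -> float:
    """Beak volume increase whose SVR gain equals ``target_delta_svr``.

    Deterministic bisection (Brent) on gfrac ∈ [0, ``max_gfrac``]; the
    returned root reproduces the target ΔSVR to better than 1e-10.  Raises if
    the target is unreachable within the bracket (e.g. the cone's own SVR does
    not exceed the composite SVR, so growing it cannot raise SVR enough).
    """
    if target_delta_svr <= 0:
        raise ValueError("target ΔSVR must be positive")
    base = composite_svr(g).svr

    def gap(x: float) -> float:
        return composite_svr(grow_beak(g, x)).svr - base - target_delta_svr

    lo, hi = 0.0, max_gfrac
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target ΔSVR {target_delta_svr:g} not reachable with beak growth in "
            f"[0, {max_gfrac:g}]"
        )
    return brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)


def _pure_body_reduction(g: BodyGeometry, target_delta_svr: float) -> float:
    """Body volume reduction whose SVR gain equals the target (bisection)."""
    base = composite_svr(g).svr

    def gap(f: float) -> float:
        return composite_svr(shrink_body(g, f)).svr - base - target_delta_svr

    hi = 1.0 - 1e-12
    if gap(0.0) > 0 or gap(hi) < 0:
        raise ValueError("target ΔSVR not reachable with body shrinkage alone")
    return brentq(gap, 0.0, hi, xtol=1e-14, rtol=8.9e-16)


def complementarity_curve(
    g: BodyGeometry, delta_svr: float, n_points: int = 21
) -> pd.DataFrame:
    """Iso-ΔSVR curve: pairs (f, gfrac) of joint body-shrink and beak-growth.

    The endpoints are the two single-trait solutions (f = 0 with the full
    compensating beak growth; gfrac = 0 with the full body reduction); interior
    points achieve the same ΔSVR with strictly smaller changes in both traits.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    base = composite_svr(g).svr
    f_pure = _pure_body_reduction(g, delta_svr)
    rows = []
    for f in np.linspace(0.0, f_pure, n_points):
        shrunk = shrink_body(g, f)
        remaining = delta_svr - (composite_svr(shrunk).svr - base)
        if remaining <= 1e-14:
            gfrac = 0.0
        else:
            gfrac = compensating_beak_increase(shrunk, remaining)
        rows.append({"f": f, "gfrac": gfrac, "delta_svr": delta_svr})
    return pd.DataFrame(rows)


def proxy_simulation(
    n: int,
    seed: int,
    k_bill: float = 0.3,
    allometry: float = 0.33,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Conical-bill proxy check: surface area tracks absolute, not relative, size.

    Simulates ``n`` conical bills with base radius proportional to height.
    Bill height is allometrically coupled to an independent lognormal body
    size (exponent ``allometry``) plus lognormal noise; "relative size" is the
    residual of ln bill height on ln body size.  Because surface area of a
    fixed-shape cone is proportional to h², its rank correlation with absolute
    bill size is exactly 1, while its correlation with relative size is
    attenuated by the shared allometric component.
    """
    if n < 10:
        raise ValueError("need at least 10 simulated bills")
    rng = np.random.default_rng(seed)
    ln_body = rng.normal(3.9, 1.0, size=n)
    ln_h = -1.0 + allometry * ln_body + rng.normal(0.0, noise_sd, size=n)
    h = np.exp(ln_h)
    r = k_bill * h
    surface = _cone_surface(h, r)
    resid = ln_h - np.polyval(np.polyfit(ln_body, ln_h, 1), ln_body)
    return pd.DataFrame(
        {
            "ln_body_size": ln_body,
            "absolute_size": h,
            "relative_size": resid,
            "surface_area": surface,
        }
    )


def proxy_correlations(table: pd.DataFrame) -> dict[str, float]:
    """Spearman correlations of surface area with absolute and relative size."""
    rho_abs = spearmanr(table["surface_area"], table["absolute_size"]).statistic
    rho_rel = spearmanr(table["surface_area"], table["relative_size"]).statistic
    return {"absolute": float(rho_abs), "relative": float(rho_rel)}
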