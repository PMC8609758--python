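"""Sleeve-tolerance ("intrinsic error") model of a guided-drilling template.

A bur of shank diameter *d* running through a sleeve of bore diameter *D*
and height *h* has diametral play ``gap = D - d``.  The worst tilt the
sleeve mechanically permits is obtained when the shank pivots across the
full diametral play over the sleeve height:

    max_angle = arctan(gap / h)

For the templates studied here (bore 1.09 mm, shank 1.0 mm, height 3 mm)
this bound is arctan(0.09/3) = 1.7184 degrees.  The same geometry bounds
the lateral displacement of the bur tip a drilling depth *z* beyond the
sleeve exit by ``gap + tan(max_angle) * z``.

:func:`simulate_sleeve_poses` is the Monte-Carlo companion: bur placements
are drawn uniformly over the mechanically feasible set (entry offset on
the clearance disc, tilt azimuth uniform, tilt magnitude uniform up to the
position-dependent maximum keeping the shank inside the bore over the full
sleeve height).  Every sampled tilt respects the analytic bound; the
sample maximum approaches it as the sample grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_geometry import SleeveSpec

__all__ = [
    "SleeveToleranceResult",
    "max_angular_error",
    "max_tip_offset",
    "sleeve_tolerance",
    "simulate_sleeve_poses",
]


@dataclass(frozen=True)
class SleeveToleranceResult:
    """Analytic tolerance summary of one sleeve at one drilling depth."""

    clearance_mm: float
    max_angle_deg: float
    max_tip_offset_mm: float
    depth_beyond_sleeve_mm: float


def max_angular_error(s: SleeveSpec) -> float:
    """Maximal sleeve-permitted tilt, degrees: ``arctan(clearance / height)``."""
    return float(np.degrees(np.arctan(s.clearance_mm / s.height_mm)))


def max_tip_offset(s: SleeveSpec, depth_beyond_sleeve_mm: float) -> float:
    """Worst-case lateral bur-tip displacement at a drilling depth beyond the
    sleeve exit: the full diametral play plus the tilt propagated over depth."""
    if depth_beyond_sleeve_mm < 0:
        raise ValueError("depth_beyond_sleeve_mm must be non-negative")
    ang = np.radians(max_angular_error(s))
    return float(s.clearance_mm + np.tan(ang) * depth_beyond_sleeve_mm)


def sleeve_tolerance(s: SleeveSpec, depth_beyond_sleeve_mm: float) -> SleeveToleranceResult:
    return SleeveToleranceResult(
        clearance_mm=s.clearance_mm,
        max_angle_deg=max_angular_error(s),
        max_tip_offset_mm=max_tip_offset(s, depth_beyond_sleeve_mm),
        depth_beyond_sleeve_mm=float(depth_beyond_sleeve_mm),
    )


def simulate_sleeve_poses(
    s: SleeveSpec,
    n: int,
    depth_beyond_sleeve_mm: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Draw ``n`` mechanically feasible bur placements through the sleeve.

    Parameterisation (an uninformative mechanical prior): the shank entry
    point is uniform on the disc of radius ``clearance/2`` about the bore
    centre; the tilt azimuth is uniform; the tilt magnitude is uniform up
    to the largest angle that keeps the shank inside the bore over the
    full sleeve height from that entry point.

    Returns a DataFrame with columns ``tilt_deg`` (tilt against the bore
    axis) and ``tip_offset_mm`` (lateral displacement of the bur tip from
    the bore axis at ``depth_beyond_sleeve_mm`` below the sleeve exit).
    Reproducible under a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if depth_beyond_sleeve_mm < 0:
        raise ValueError("depth_beyond_sleeve_mm must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    c = s.clearance_mm / 2.0  # radial play
    h = s.height_mm
    rho = c * np.sqrt(rng.random(n))  # entry offset, uniform on the disc
    psi = rng.uniform(0.0, 2.0 * np.pi, n)  # azimuth of tilt relative to entry offset
    # largest across-sleeve displacement keeping the exit inside the bore
    s_cap = np.sqrt(np.maximum(c**2 - (rho * np.sin(psi)) ** 2, 0.0)) - rho * np.cos(psi)
    s_cap = np.minimum(s_cap, 2.0 * c)  # guards rounding at the pivot extreme
    theta_cap = np.arctan2(s_cap, h)
    theta = theta_cap * rng.random(n)

    reach = (h + depth_beyond_sleeve_mm) * np.tan(theta)
    tip_offset = np.hypot(rho + reach * np.cos(psi), reach * np.sin(psi))
    return pd.DataFrame({"tilt_deg": np.degrees(theta), "tip_offset_mm": tip_offset})
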