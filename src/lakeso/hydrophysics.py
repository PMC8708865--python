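"""Water-column stratification metrics from temperature profiles.

A stratified lake separates into a warm upper mixed layer (epilimnion), a
transition layer with a strong density gradient (metalimnion) and a cold
bottom layer (hypolimnion).  The metrics computed here follow the standard
limnological density-gradient algorithm:

* the thermocline is the depth at which the vertical density gradient is
  maximal;
* the metalimnion is bounded by the depths at which the gradient falls
  below a fixed threshold (0.1 kg m-3 m-1 by default) on either side of
  the thermocline.

Density is derived from temperature with the Martin & McCutcheon
fresh-water polynomial (zero salinity), the formula used by common
limnology toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DepthProfile",
    "StratificationMetrics",
    "water_density",
    "density_gradient",
    "thermocline_depth",
    "metalimnion_bounds",
    "stratification_metrics",
    "DENSITY_GRADIENT_THRESHOLD",
    "MIN_STRATIFICATION_GRADIENT",
]

#: metalimnion boundary threshold, kg m-3 m-1
DENSITY_GRADIENT_THRESHOLD = 0.1
#: minimum peak density gradient for a column to count as stratified,
#: kg m-3 m-1; below this the thermocline is reported as undefined
MIN_STRATIFICATION_GRADIENT = 0.05


@dataclass(frozen=True)
class DepthProfile:
    """One scalar quantity sampled at strictly increasing depths.

    Used both for temperature (deg C) and for single-group chlorophyll
    profiles; ``basin`` and ``time`` are free-form event metadata.
    """

    depths: np.ndarray
    values: np.ndarray
    basin: Optional[str] = None
    time: Optional[object] = None

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if depths.ndim != 1 or values.ndim != 1:
            raise ValueError("depths and values must be one-dimensional")
        if depths.size != values.size:
            raise ValueError(
                f"depths ({depths.size}) and values ({values.size}) differ in length"
            )
        if depths.size and np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if depths.size and depths[0] < 0:
            raise ValueError("depths must be non-negative")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.depths.size


@dataclass(frozen=True)
class StratificationMetrics:
    """Per-event stratification summary.

    All depth fields are ``None`` when the column is effectively mixed
    (no gradient reaches ``MIN_STRATIFICATION_GRADIENT``) or when the
    gradient never reaches the metalimnion threshold.
    """

    thermo_depth: Optional[float]
    meta_upper: Optional[float]
    meta_lower: Optional[float]
    stratified: bool

    @property
    def meta_width(self) -> Optional[float]:
        if self.meta_upper is None or self.meta_lower is None:
            return None
        return self.meta_lower - self.meta_upper


def water_density(temperature):
    """Fresh-water density (kg m-3) from temperature (deg C).

    Martin & McCutcheon polynomial at zero salinity::

        rho(T) = 1000 * (1 - (T + 288.9414) / (508929.2 * (T + 68.12963))
                              * (T - 3.9863)**2)

    Exactly 1000 at the density maximum T = 3.9863 deg C and strictly
    decreasing above it.  Valid for -5 <= T <= 40.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < -5.0) or np.any(t > 40.0):
        raise ValueError("temperature outside the supported range [-5, 40] deg C")
    rho = 1000.0 * (
        1.0 - ((t + 288.9414) / (508929.2 * (t + 68.12963))) * (t - 3.9863) ** 2
    )
    return rho if rho.ndim else float(rho)


def density_gradient(profile: DepthProfile) -> DepthProfile:
    """Density gradient (kg m-3 m-1) between adjacent sensors.

    Finite differences of density located at layer midpoints; the result
    has ``len(profile) - 1`` points.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 depths for a gradient")
    rho = water_density(profile.values)
    dz = np.diff(profile.depths)
    grad = np.diff(rho) / dz
    mid = 0.5 * (profile.depths[:-1] + profile.depths[1:])
    return DepthProfile(mid, grad, basin=profile.basin, time=profile.time)


def thermocline_depth(
    profile: DepthProfile,
    min_gradient: float = MIN_STRATIFICATION_GRADIENT,
    smooth_window: Optional[int] = None,
) -> Optional[float]:
    """Depth of the maximal density gradient, or ``None`` if unstratified.

    Ties are broken in favour of the shallowest maximum.  ``smooth_window``
    applies a centred moving average (odd width, in layers) to the gradient
    series before locating the maximum; off by default.
    """
    grad = density_gradient(profile)
    g = grad.values
    if smooth_window is not None and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    k = int(np.argmax(g))  # argmax returns the first (shallowest) maximum
    if g[k] < min_gradient:
        return None
    return float(grad.depths[k])


def metalimnion_bounds(
    profile: DepthProfile,
    threshold: float = DENSITY_GRADIENT_THRESHOLD,
    min_gradient: float = MIN_STRATIFICATION_GRADIENT,
):
    """Upper and lower metalimnion depths, or ``None`` when undefined.

    Starting from the thermocline layer, the gradient series is scanned
    upward and downward for the first layer whose gradient drops below
    ``threshold``; the crossing depth is linearly interpolated between
    layer midpoints.  If the gradient never drops below the threshold on
    one side, the bound is clamped to the corresponding profile end.
    Returns ``None`` when the column is unstratified or when the maximal
    gradient itself is below ``threshold``.
    """
    grad = density_gradient(profile)
    g, mid = grad.values, grad.depths
    k = int(np.argmax(g))
    if g[k] < min_gradient or g[k] < threshold:
        return None

    def _cross(j_inner: int, j_outer: int) -> float:
        # gradient crosses `threshold` between midpoints j_inner (>= thr)
        # and j_outer (< thr)
        g0, g1 = g[j_inner], g[j_outer]
        frac = (g0 - threshold) / (g0 - g1)
        return float(mid[j_inner] + frac * (mid[j_outer] - mid[j_inner]))

    upper = float(profile.depths[0])
    for j in range(k - 1, -1, -1):
        if g[j] < threshold:
            upper = _cross(j + 1, j)
            break
    lower = float(profile.depths[-1])
    for j in range(k + 1, g.size):
        if g[j] < threshold:
            lower = _cross(j - 1, j)
            break
    return upper, lower


def stratification_metrics(
    profile: DepthProfile,
    threshold: float = DENSITY_GRADIENT_THRESHOLD,
    min_gradient: float = MIN_STRATIFICATION_GRADIENT,
    smooth_window: Optional[int] = None,
) -> StratificationMetrics:
    """Thermocline depth and metalimnion bounds for one profile."""
    td = thermocline_depth(profile, min_gradient=min_gradient, smooth_window=smooth_window)
    if td is None:
        return StratificationMetrics(None, None, None, stratified=False)
    bounds = metalimnion_bounds(profile, threshold=threshold, min_gradient=min_gradient)
    if bounds is None:
        return StratificationMetrics(td, None, None, stratified=True)
    upper, lower = bounds
    # numerical guard: the thermocline midpoint always lies inside the band
    upper = min(upper, td)
    lower = max(lower, td)
    return StratificationMetrics(td, upper, lower, stratified=True)
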