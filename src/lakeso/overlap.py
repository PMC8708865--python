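"""Vertical spatial overlap (SO) between phytoplankton spectral groups.

A depth-profiling fluorometer resolves chlorophyll *a* for four spectral
groups (BROWNS, GREENS, CYANOS, MIXED).  For one sampling event each
group's vertical distribution is turned into a unit-area kernel density
over depth, and SO is the mean over group pairs of the shared area under
the two density curves (the kernel analogue of Schoener's niche-overlap
index):

    O(a, b) = integral min(f_a(z), f_b(z)) dz          in [0, 1]
    SO      = mean of O over all pairs of present groups

0 means fully segregated distributions, 1 identical distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "SPECTRAL_GROUPS",
    "SpectralProfileSet",
    "OverlapResult",
    "depth_density",
    "pairwise_overlap",
    "spatial_overlap",
]

#: canonical spectral group order
SPECTRAL_GROUPS = ("browns", "greens", "cyanos", "mixed")

#: column-integrated concentration (ug L-1 * m) below which a group is
#: treated as absent
DETECTION_FLOOR = 0.05

#: number of evaluation-grid points over the water column
N_GRID = 512


@dataclass(frozen=True)
class SpectralProfileSet:
    """Chlorophyll-a profiles of the four spectral groups for one event."""

    depths: np.ndarray
    concentrations: Dict[str, np.ndarray]
    basin: Optional[str] = None
    time: Optional[object] = None

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        if depths.ndim != 1 or depths.size < 2:
            raise ValueError("need a one-dimensional depth grid with >= 2 points")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        conc = {}
        for name, c in self.concentrations.items():
            c = np.asarray(c, dtype=float)
            if c.shape != depths.shape:
                raise ValueError(f"group {name!r} not on the shared depth grid")
            if np.any(c < 0):
                raise ValueError(f"group {name!r} has negative concentrations")
            conc[name] = c
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "concentrations", conc)

    def column_total(self, group: str) -> float:
        """Trapezoidal column integral of one group (ug L-1 * m)."""
        return float(np.trapezoid(self.concentrations[group], self.depths))


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlaps and their mean (SO) for one event."""

    pairwise: Dict[Tuple[str, str], float]
    so: Optional[float]
    groups_used: Tuple[str, ...]


def _silverman_bandwidth(depths: np.ndarray, weights: np.ndarray) -> float:
    """Silverman rule-of-thumb on concentration-weighted depth moments.

    h = 0.9 * min(sigma, IQR / 1.34) * n_eff**(-1/5), with the effective
    sample size n_eff = (sum w)^2 / sum w^2.
    """
    w = weights / weights.sum()
    mu = float(w @ depths)
    sigma = float(np.sqrt(w @ (depths - mu) ** 2))
    order = np.argsort(depths)
    cw = np.cumsum(w[order])
    q25, q75 = np.interp([0.25, 0.75], cw, depths[order])
    iqr = q75 - q25
    n_eff = weights.sum() ** 2 / np.sum(weights**2)
    spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
    if spread <= 0:
        # degenerate (all mass at one depth): fall back to grid spacing
        spread = float(np.min(np.diff(np.unique(depths)))) or 1e-3
    return 0.9 * spread * n_eff ** (-0.2)


def depth_density(
    depths,
    concentrations,
    grid,
    bandwidth: Optional[float] = None,
    reflect: bool = True,
) -> np.ndarray:
    """Unit-area Gaussian kernel density of depth weighted by concentration.

    Each measurement depth contributes a Gaussian kernel weighted by its
    concentration.  With ``reflect=True`` (default) kernel mass leaking
    past the surface and the bottom of the grid is folded back in, so a
    uniform profile stays close to uniform.  The result is renormalized
    to integrate to exactly 1 over ``grid`` (trapezoidal rule).
    """
    z = np.asarray(depths, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("depth_density needs positive total concentration")
    w = c / total
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(z, c)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    def _kde(points: np.ndarray) -> np.ndarray:
        u = (grid[:, None] - points[None, :]) / h
        return np.exp(-0.5 * u**2) @ w

    dens = _kde(z)
    if reflect:
        top, bottom = grid[0], grid[-1]
        dens = dens + _kde(2 * top - z) + _kde(2 * bottom - z)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density (zero area); widen the bandwidth")
    return dens / area


def pairwise_overlap(density_a, density_b, grid) -> float:
    """Shared area under two unit-area density curves on a common grid."""
    fa = np.asarray(density_a, dtype=float)
    fb = np.asarray(density_b, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if fa.shape != grid.shape or fb.shape != grid.shape:
        raise ValueError("densities and grid must share one shape")
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def spatial_overlap(
    profiles: SpectralProfileSet,
    n_grid: int = N_GRID,
    bandwidth: Optional[float] = None,
    reflect: bool = True,
    detection_floor: float = DETECTION_FLOOR,
    absent_as_zero: bool = False,
) -> OverlapResult:
    """SO index for one event: mean pairwise overlap of present groups.

    Groups whose column-integrated concentration falls below
    ``detection_floor`` are treated as absent.  By default absent groups
    are excluded from the pairwise mean; with ``absent_as_zero=True``
    pairs involving an absent group count as overlap 0 instead
    (a sensitivity option).  SO is ``None`` when fewer than two groups
    are present.
    """
    names = [g for g in SPECTRAL_GROUPS if g in profiles.concentrations]
    names += [g for g in profiles.concentrations if g not in names]
    present = [g for g in names if profiles.column_total(g) >= detection_floor]
    grid = np.linspace(profiles.depths[0], profiles.depths[-1], n_grid)
    dens = {
        g: depth_density(
            profiles.depths,
            profiles.concentrations[g],
            grid,
            bandwidth=bandwidth,
            reflect=reflect,
        )
        for g in present
    }
    pairwise: Dict[Tuple[str, str], float] = {}
    included = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in dens and b in dens:
                o = pairwise_overlap(dens[a], dens[b], grid)
                pairwise[(a, b)] = min(1.0, max(0.0, o))
                included.append(pairwise[(a, b)])
            elif absent_as_zero:
                pairwise[(a, b)] = 0.0
                included.append(0.0)
            else:
                pairwise[(a, b)] = float("nan")
    if len(present) < 2:
        return OverlapResult(pairwise, None, tuple(present))
    return OverlapResult(pairwise, float(np.mean(included)), tuple(present))
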