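"""Taxonomic and functional diversity indices for phytoplankton communities.

The community is an events x genera biomass matrix (biovolume-derived,
mm3 m-3) paired with a genera x traits matrix of six functional traits:
maximum linear dimension (MLD, um, quantitative), nitrogen fixation,
silica fixation, mixotrophy, coloniality (binary Y/N) and pigment type
(nominal, 5 levels).  Indices:

* Shannon H' (nats) on biomass shares;
* functional dispersion F_Dis: biomass-weighted mean distance of genera
  to the biomass-weighted community centroid in the principal-coordinate
  embedding of the Gower trait dissimilarities (negative eigenvalues kept
  as imaginary axes, Anderson-style);
* community-weighted variance of MLD (CWvar, um^2), no small-sample
  correction;
* per-trait Shannon diversity over the biomass totals of trait
  modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_COLUMNS",
    "DiversityRecord",
    "shannon",
    "gower_dissimilarity",
    "fdis",
    "cwvar",
    "trait_modality_shannon",
    "community_diversity",
]

#: trait columns expected in a trait matrix; MLD is quantitative, the rest
#: categorical
TRAIT_COLUMNS = ("mld", "n_fixation", "si_fixation", "mixotrophy", "coloniality", "pigment")
PIGMENT_LEVELS = ("Brown", "Green", "Blue-Green", "Yellow", "Red")


@dataclass(frozen=True)
class DiversityRecord:
    """All per-event diversity indices."""

    h_prime: float
    f_dis: float
    cwvar_mld: float
    h_nfix: float
    h_si: float
    h_mix: float
    h_col: float
    h_pig: float


def _shares(biomass) -> np.ndarray:
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    total = b.sum()
    if total <= 0:
        raise ValueError("all-zero biomass vector: event has no community")
    return b / total


def shannon(biomass, base: Optional[float] = None) -> float:
    """Shannon diversity H' = -sum p_i log p_i on biomass shares.

    Natural log by default (nats); zero-biomass taxa are ignored.
    """
    p = _shares(biomass)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def gower_dissimilarity(traits: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarities between genera on a mixed trait matrix.

    Quantitative traits contribute |x_i - x_j| / range (range taken over
    the full matrix); categorical traits contribute a 0/1 mismatch.  The
    per-trait contributions are averaged over traits where both genera
    are non-missing.  Quantitative traits with zero range are dropped
    with a warning.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 genera for dissimilarities")
    n = len(traits)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in traits.columns:
        x = traits[col]
        valid = x.notna().to_numpy()
        both = np.outer(valid, valid)
        if pd.api.types.is_numeric_dtype(x):
            v = x.to_numpy(dtype=float)
            rng = np.nanmax(v) - np.nanmin(v)
            if rng == 0:
                warnings.warn(
                    f"quantitative trait {col!r} has zero range; dropped from Gower",
                    stacklevel=2,
                )
                continue
            with np.errstate(invalid="ignore"):
                contrib = np.abs(v[:, None] - v[None, :]) / rng
            contrib = np.where(both, contrib, 0.0)
        else:
            v = x.to_numpy()
            contrib = np.where(both, (v[:, None] != v[None, :]).astype(float), 0.0)
        num += contrib
        den += both
    if np.any(den == 0):
        raise ValueError("some genus pair shares no non-missing trait")
    d = num / den
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


def _pcoa_axes(d: np.ndarray):
    """Principal-coordinate axes of a dissimilarity matrix.

    Returns (real_axes, imaginary_axes): coordinates on axes with
    positive and negative eigenvalues respectively.  Non-Euclidean parts
    of the Gower metric end up on the imaginary axes and enter squared
    distances with a negative sign.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-10 * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def fdis(biomass, traits: Optional[pd.DataFrame] = None, dissimilarity=None) -> float:
    """Functional dispersion F_Dis of one community.

    Biomass-weighted mean distance of genera to the biomass-weighted
    centroid in the principal-coordinate embedding of the Gower
    dissimilarities.  Squared distances on negative-eigenvalue axes are
    subtracted (clipped at zero), so the index matches the standard
    mixed-trait implementation.  Invariant to rescaling of biomass;
    a single present genus gives 0.
    """
    w = _shares(biomass)
    if dissimilarity is None:
        if traits is None:
            raise ValueError("provide either a trait matrix or a dissimilarity matrix")
        if len(traits) != w.size:
            raise ValueError("trait matrix does not cover the biomass vector")
        if w.size == 1 or (w > 0).sum() == 1:
            return 0.0
        dissimilarity = gower_dissimilarity(traits)
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape != (w.size, w.size):
        raise ValueError("dissimilarity matrix does not match the biomass vector")
    if (w > 0).sum() == 1:
        return 0.0
    real, imag = _pcoa_axes(d)
    c_real = w @ real
    c_imag = w @ imag
    z2 = ((real - c_real) ** 2).sum(axis=1) - ((imag - c_imag) ** 2).sum(axis=1)
    z = np.sqrt(np.clip(z2, 0.0, None))
    return float(w @ z)


def cwvar(biomass, values) -> float:
    """Community-weighted variance of a quantitative trait.

    CWM = sum p_i x_i; CWvar = sum p_i (x_i - CWM)^2 with p_i the biomass
    shares.  No small-sample correction.
    """
    w = _shares(biomass)
    x = np.asarray(values, dtype=float)
    if x.shape != w.shape:
        raise ValueError("trait values do not match the biomass vector")
    cwm = float(w @ x)
    return float(w @ (x - cwm) ** 2)


def trait_modality_shannon(biomass, modalities, base: Optional[float] = None) -> float:
    """Shannon diversity over trait modalities rather than taxa.

    Biomass is summed within each modality of the trait (e.g. mixotroph
    vs non-mixotroph, or the five pigment types) and H' is applied to the
    modality totals.
    """
    w = np.asarray(biomass, dtype=float)
    m = pd.Series(modalities)
    if len(m) != w.size:
        raise ValueError("modalities do not match the biomass vector")
    totals = pd.Series(w).groupby(m.to_numpy()).sum()
    return shannon(totals.to_numpy(), base=base)


def community_diversity(
    biomass: Sequence[float],
    traits: pd.DataFrame,
    dissimilarity=None,
) -> DiversityRecord:
    """All diversity indices for one event's biomass vector.

    ``traits`` rows must align with the biomass vector and carry the
    columns in :data:`TRAIT_COLUMNS`.
    """
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValueError(f"trait matrix lacks columns: {missing}")
    return DiversityRecord(
        h_prime=shannon(biomass),
        f_dis=fdis(biomass, traits[list(TRAIT_COLUMNS)], dissimilarity=dissimilarity),
        cwvar_mld=cwvar(biomass, traits["mld"].to_numpy(dtype=float)),
        h_nfix=trait_modality_shannon(biomass, traits["n_fixation"]),
        h_si=trait_modality_shannon(biomass, traits["si_fixation"]),
        h_mix=trait_modality_shannon(biomass, traits["mixotrophy"]),
        h_col=trait_modality_shannon(biomass, traits["coloniality"]),
        h_pig=trait_modality_shannon(biomass, traits["pigment"]),
    )
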