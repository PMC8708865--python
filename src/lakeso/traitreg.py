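"""Permutation-tested multiple linear regressions of trait-diversity indices.

Each trait-variability index (CWvar of cell size, per-trait Shannon
diversities) is regressed on the four event-level predictors: thermocline
depth, metalimnion width, log cladoceran biomass and SO.  Coefficients
are ordinary least squares; their significance comes from a permutation
test that shuffles the response vector and compares permuted |t|
statistics with the observed one:

    p = (#{ |t*| >= |t_obs| } + 1) / (n_perm + 1)      (two-tailed)

A through-origin mode (no intercept) and a residual-permutation scheme
(Freedman-Lane) are available as sensitivity options.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PermRegressionResult", "perm_lm", "trait_regression_table"]

#: default Table-shaped analysis: responses and predictors
TRAIT_RESPONSES = ("cwvar_mld", "h_nfix", "h_si", "h_mix", "h_col", "h_pig")
PREDICTORS = ("thermo_depth", "meta_width", "log_cladocera_biom", "so")


@dataclass(frozen=True)
class PermRegressionResult:
    """Least-squares coefficients with permutation p-values."""

    response: str
    coefficients: pd.Series
    p_values: pd.Series
    t_values: pd.Series
    n_perm: int
    through_origin: bool
    r_squared: float


def _design(x: pd.DataFrame, through_origin: bool) -> np.ndarray:
    m = x.to_numpy(dtype=float)
    if not through_origin:
        m = np.column_stack([np.ones(len(m)), m])
    return m


def _t_stats(xtx_inv_diag, coef, resid_ss, dof):
    # vectorised over permutation columns
    sigma2 = resid_ss / dof
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, coef / se, np.inf * np.sign(coef))


def perm_lm(
    response,
    predictors: pd.DataFrame,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    through_origin: bool = False,
    scheme: str = "response",
) -> PermRegressionResult:
    """Multiple regression with permutation p-values per coefficient.

    ``scheme="response"`` permutes the raw response (default);
    ``scheme="freedman_lane"`` permutes residuals of the reduced model
    excluding each coefficient's predictor, a common alternative when
    covariates are influential.
    """
    y = np.asarray(response, dtype=float).ravel()
    x = _design(predictors, through_origin)
    n, k = x.shape
    if n <= k:
        raise ValueError("need more events than coefficients")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("collinear predictors: design matrix is rank-deficient")
    if scheme not in ("response", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    names = list(predictors.columns)
    if not through_origin:
        names = ["intercept"] + names
    xtx_inv = np.linalg.inv(x.T @ x)
    proj = xtx_inv @ x.T
    dof = n - k

    coef = proj @ y
    resid = y - x @ coef
    ss_res = float(resid @ resid)
    t_obs = _t_stats(np.diag(xtx_inv), coef[:, None], np.array([ss_res]), dof)[:, 0]
    ss_tot = float(((y - y.mean()) ** 2).sum()) if not through_origin else float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = np.zeros(k)
    chunk = 500

    def _perm_t(y_perm: np.ndarray) -> np.ndarray:
        # y_perm: n x b -> t statistics, k x b, under the full model
        coef_p = proj @ y_perm
        resid_p = y_perm - x @ coef_p
        ss_p = (resid_p**2).sum(axis=0)
        return _t_stats(np.diag(xtx_inv), coef_p, ss_p, dof)

    if scheme == "response":
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            idx = np.argsort(rng.random((b, n)), axis=1)
            exceed += (
                np.abs(_perm_t(y[idx].T)) >= np.abs(t_obs)[:, None] - 1e-12
            ).sum(axis=1)
            done += b
    else:
        # Freedman-Lane: for each coefficient, permute the residuals of the
        # reduced model that omits its predictor, add back the reduced fit,
        # and recompute that coefficient's t under the full model
        for j in range(k):
            xr = np.delete(x, j, axis=1)
            if xr.shape[1]:
                fit_r = xr @ np.linalg.lstsq(xr, y, rcond=None)[0]
            else:
                fit_r = np.zeros(n)
            e_r = y - fit_r
            done = 0
            while done < n_perm:
                b = min(chunk, n_perm - done)
                idx = np.argsort(rng.random((b, n)), axis=1)
                t_p = _perm_t(fit_r[:, None] + e_r[idx].T)
                exceed[j] += (np.abs(t_p[j]) >= abs(t_obs[j]) - 1e-12).sum()
                done += b
    p = (exceed + 1.0) / (n_perm + 1.0)

    resp_name = getattr(response, "name", None) or "response"
    return PermRegressionResult(
        response=str(resp_name),
        coefficients=pd.Series(coef, index=names),
        p_values=pd.Series(p, index=names),
        t_values=pd.Series(t_obs, index=names),
        n_perm=n_perm,
        through_origin=through_origin,
        r_squared=r2,
    )


def trait_regression_table(
    events: pd.DataFrame,
    responses: Sequence[str] = TRAIT_RESPONSES,
    predictors: Sequence[str] = PREDICTORS,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    through_origin: bool = False,
) -> pd.DataFrame:
    """One permutation regression per trait index; wide coefficient/p table.

    Rows are the responses; columns interleave each predictor's
    coefficient and permutation p-value.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for resp in responses:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = perm_lm(
            events[resp],
            events[list(predictors)],
            n_perm=n_perm,
            seed=sub_seed,
            through_origin=through_origin,
        )
        row = {}
        for pred in predictors:
            row[f"{pred}_coef"] = res.coefficients[pred]
            row[f"{pred}_p"] = res.p_values[pred]
        rows[resp] = row
    return pd.DataFrame.from_dict(rows, orient="index")
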