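"""Recursive observed-variable path models fitted by maximum likelihood.

The analysis links five observed variables: two exogenous descriptors of
the lake's physical structure (thermocline depth, metalimnion width) and
three endogenous ones (log cladoceran biomass, spatial overlap SO, and a
phytoplankton diversity index).  The default structure sends both
exogenous variables to every endogenous one, plus cladoceran biomass and
SO to diversity — eight directed paths, leaving one overidentifying
constraint (df = 1): the residuals of cladoceran biomass and SO are
uncorrelated.

Fitting minimises the ML covariance discrepancy

    F(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

over the free parameters (path coefficients and log residual variances;
the exogenous covariance block is saturated, i.e. fixed at its sample
values, the conventional path-analysis treatment).  chi2 = (N - 1) F_min
is referred to the chi-square distribution with the model's df; GFI and
per-equation R2 are derived from the fitted covariance.  Inference on
the paths uses a nonparametric bootstrap (resampling events) with a
normal-approximation p-value from the bootstrap standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "BootstrapResult",
    "default_spec",
    "parse_model",
    "fit_ml",
    "bootstrap_inference",
    "autocorrelation_screen",
]

DEFAULT_ENDOGENOUS_ORDER = ("Cladocera_Biom", "SO", "Diversity")


@dataclass(frozen=True)
class PathModelSpec:
    """Directed-path structure among named observed variables."""

    exogenous: Tuple[str, ...]
    paths: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        order = self._topological_order()
        if not set(self.exogenous) <= set(order):
            # exogenous variables with no outgoing path are still variables
            pass
        for src, tgt in self.paths:
            if tgt in self.exogenous:
                raise ValueError(f"exogenous variable {tgt!r} cannot be a path target")

    @property
    def endogenous(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for _, tgt in self.paths:
            if tgt not in seen:
                seen.append(tgt)
        return tuple(self._topological_order_endo(seen))

    @property
    def variables(self) -> Tuple[str, ...]:
        return tuple(self.exogenous) + self.endogenous

    def parents(self, var: str) -> Tuple[str, ...]:
        return tuple(src for src, tgt in self.paths if tgt == var)

    def _topological_order(self) -> List[str]:
        nodes = list(dict.fromkeys(list(self.exogenous) + [v for p in self.paths for v in p]))
        incoming = {v: set(src for src, tgt in self.paths if tgt == v) for v in nodes}
        order: List[str] = []
        ready = [v for v in nodes if not incoming[v]]
        while ready:
            v = ready.pop(0)
            order.append(v)
            for w in nodes:
                if v in incoming[w]:
                    incoming[w].discard(v)
                    if not incoming[w] and w not in order and w not in ready:
                        ready.append(w)
        if len(order) != len(nodes):
            raise ValueError("path graph contains a cycle")
        return order

    def _topological_order_endo(self, endo: Sequence[str]) -> List[str]:
        return [v for v in self._topological_order() if v in endo]

    @property
    def n_free_parameters(self) -> int:
        k = len(self.exogenous)
        # saturated exogenous block + paths + endogenous residual variances
        return k * (k + 1) // 2 + len(self.paths) + len(self.endogenous)

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_parameters

    @classmethod
    def saturated(cls, exogenous: Sequence[str], endogenous: Sequence[str]) -> "PathModelSpec":
        """Fully recursive model (every earlier variable points at every
        later one); reproduces any sample covariance exactly (df = 0)."""
        order = list(exogenous) + list(endogenous)
        paths = []
        for j, tgt in enumerate(order):
            if tgt in exogenous:
                continue
            paths.extend((src, tgt) for src in order[:j])
        return cls(tuple(exogenous), tuple(paths))


def default_spec(diversity: str = "Diversity") -> PathModelSpec:
    """The study's hypothesis graph with a configurable diversity label."""
    exo = ("Thermo_Depth", "Meta_Width")
    endo = ("Cladocera_Biom", "SO", diversity)
    paths = [(x, y) for y in endo for x in exo]
    paths += [("Cladocera_Biom", diversity), ("SO", diversity)]
    return PathModelSpec(exo, tuple(paths))


def parse_model(text: str, exogenous: Sequence[str]) -> PathModelSpec:
    """Parse plain-text path syntax: one ``target ~ src1 + src2`` line per
    endogenous variable; blank lines and ``#`` comments are ignored."""
    paths: List[Tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~" not in line:
            raise ValueError(f"line {lineno}: expected 'target ~ sources', got {raw!r}")
        tgt, rhs = (s.strip() for s in line.split("~", 1))
        for src in (s.strip() for s in rhs.split("+")):
            if not src:
                raise ValueError(f"line {lineno}: empty source term")
            paths.append((src, tgt))
    return PathModelSpec(tuple(exogenous), tuple(paths))


@dataclass(frozen=True)
class PathModelFit:
    """ML fit of a recursive path model."""

    spec: PathModelSpec
    n: int
    estimates: pd.DataFrame  # rows: (source, target); cols: estimate, standardized
    residual_variances: Dict[str, float]
    chisq: float
    df: int
    p_value: float
    gfi: float
    r_squared: Dict[str, float]
    sigma: pd.DataFrame  # model-implied covariance
    sample_cov: pd.DataFrame
    converged: bool
    n_iter: int


def _check_sample_cov(s: np.ndarray, names: Sequence[str]) -> None:
    eigval = np.linalg.eigvalsh(s)
    if eigval.min() <= 1e-10 * max(1.0, eigval.max()):
        corr = s / np.sqrt(np.outer(np.diag(s), np.diag(s)))
        worst = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 0.999:
                    worst.append(f"{names[i]} ~ {names[j]}")
        detail = f" (collinear: {', '.join(worst)})" if worst else ""
        raise ValueError(f"sample covariance matrix is singular{detail}")


def _structural_matrices(theta, spec, s, var_index, exo_idx):
    p = len(var_index)
    a = np.zeros((p, p))
    for k, (src, tgt) in enumerate(spec.paths):
        a[var_index[tgt], var_index[src]] = theta[k]
    psi = np.zeros((p, p))
    psi[np.ix_(exo_idx, exo_idx)] = s[np.ix_(exo_idx, exo_idx)]
    for k, v in enumerate(spec.endogenous):
        j = var_index[v]
        psi[j, j] = np.exp(theta[len(spec.paths) + k])
    t = np.linalg.inv(np.eye(p) - a)
    sigma = t @ psi @ t.T
    return a, psi, t, sigma


def _discrepancy_and_grad(theta, spec, s, logdet_s, var_index, exo_idx):
    p = len(var_index)
    _, psi, t, sigma = _structural_matrices(theta, spec, s, var_index, exo_idx)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    sigma_inv = np.linalg.inv(sigma)
    f = logdet - logdet_s + float(np.trace(s @ sigma_inv)) - p
    # dF = tr(W dSigma), W = Sigma^-1 - Sigma^-1 S Sigma^-1
    w = sigma_inv - sigma_inv @ s @ sigma_inv
    grad = np.zeros_like(theta)
    swt = sigma @ w @ t  # for path (i <- j): dF/dA_ij = 2 (Sigma W T)[j, i]
    for k, (src, tgt) in enumerate(spec.paths):
        grad[k] = 2.0 * swt[var_index[src], var_index[tgt]]
    twt = t.T @ w @ t
    for k, v in enumerate(spec.endogenous):
        j = var_index[v]
        grad[len(spec.paths) + k] = twt[j, j] * psi[j, j]  # chain rule, log scale
    return f, grad


def fit_ml(data: pd.DataFrame, spec: PathModelSpec, gtol: float = 1e-12) -> PathModelFit:
    """Fit a recursive path model by ML on the sample covariance matrix.

    Quasi-Newton (BFGS) minimisation over the free parameters, with the
    endogenous residual variances log-parameterised for positivity and
    the exogenous covariance block fixed at its sample values.  Raises on
    a singular sample covariance or non-convergence.
    """
    variables = list(spec.variables)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model columns: {missing}")
    x = data[variables].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in model columns")
    n = x.shape[0]
    if n <= len(variables):
        raise ValueError("need more events than model variables")
    s = np.cov(x, rowvar=False, ddof=1)
    _check_sample_cov(s, variables)
    var_index = {v: i for i, v in enumerate(variables)}
    exo_idx = [var_index[v] for v in spec.exogenous]

    # optimize on the correlation scale: the ML discrepancy is invariant
    # to diagonal rescaling and the problem is far better conditioned
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    logdet_r = float(np.linalg.slogdet(r)[1])

    theta0 = np.concatenate([np.zeros(len(spec.paths)), np.zeros(len(spec.endogenous))])
    res = optimize.minimize(
        _discrepancy_and_grad,
        theta0,
        args=(spec, r, logdet_r, var_index, exo_idx),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": 2000},
    )
    # BFGS may stop on line-search precision right at the optimum; accept
    # if the gradient is essentially zero
    grad_ok = np.max(np.abs(res.jac)) < 1e-6
    if not (res.success or grad_ok):
        raise RuntimeError(
            f"ML fit did not converge: {res.message} "
            f"(|grad|_max={np.max(np.abs(res.jac)):.2e}, f={res.fun:.6g})"
        )
    # map the correlation-scale solution back to the raw scale:
    # b_raw = b_std * sd(target) / sd(source); psi_raw = psi_std * var(target)
    theta = res.x.copy()
    for k, (src, tgt) in enumerate(spec.paths):
        theta[k] *= d[var_index[tgt]] / d[var_index[src]]
    for k, v in enumerate(spec.endogenous):
        theta[len(spec.paths) + k] += 2.0 * np.log(d[var_index[v]])
    _, psi, _, sigma = _structural_matrices(theta, spec, s, var_index, exo_idx)

    f_min = max(0.0, float(res.fun))
    chisq = (n - 1) * f_min
    df = spec.df
    p_value = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    sigma_inv = np.linalg.inv(sigma)
    m = sigma_inv @ s
    gfi = 1.0 - np.trace((m - np.eye(len(variables))) @ (m - np.eye(len(variables)))) / np.trace(m @ m)

    sd = np.sqrt(np.diag(sigma))
    rows = []
    for k, (src, tgt) in enumerate(spec.paths):
        est = theta[k]
        std = est * sd[var_index[src]] / sd[var_index[tgt]]
        rows.append({"source": src, "target": tgt, "estimate": est, "standardized": std})
    estimates = pd.DataFrame(rows).set_index(["source", "target"])
    resid = {v: float(psi[var_index[v], var_index[v]]) for v in spec.endogenous}
    r2 = {v: 1.0 - resid[v] / sigma[var_index[v], var_index[v]] for v in spec.endogenous}
    return PathModelFit(
        spec=spec,
        n=n,
        estimates=estimates,
        residual_variances=resid,
        chisq=float(chisq),
        df=df,
        p_value=p_value,
        gfi=float(gfi),
        r_squared=r2,
        sigma=pd.DataFrame(sigma, index=variables, columns=variables),
        sample_cov=pd.DataFrame(s, index=variables, columns=variables),
        converged=True,
        n_iter=int(res.nit),
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap inference for the path coefficients."""

    estimates: pd.DataFrame  # estimate, se, p, ci_low, ci_high per path
    n_boot: int
    n_converged: int
    seed: Optional[int]


def bootstrap_inference(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 10000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Nonparametric bootstrap (resampling events with replacement).

    The p-value per path is the two-sided normal approximation
    2 Phi(-|estimate / SE_boot|) with SE_boot the bootstrap standard
    deviation; percentile intervals are reported alongside.  Replicates
    whose refit fails are dropped and counted; a warning is issued when
    more than 10% fail.
    """
    full = fit_ml(data, spec)
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            fit_b = fit_ml(data.iloc[idx], spec)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failed += 1
            continue
        draws.append(fit_b.estimates["estimate"].to_numpy())
    if failed > 0.1 * n_boot:
        import warnings

        warnings.warn(f"{failed} of {n_boot} bootstrap replicates failed to converge")
    boot = np.asarray(draws)
    se = boot.std(axis=0, ddof=1)
    est = full.estimates["estimate"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.inf * np.sign(est))
    p = 2.0 * stats.norm.sf(np.abs(z))
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    out = full.estimates.copy()
    out["se"] = se
    out["p"] = p
    out["ci_low"] = lo
    out["ci_high"] = hi
    return BootstrapResult(out, n_boot=n_boot, n_converged=len(draws), seed=seed)


def autocorrelation_screen(
    data: pd.DataFrame,
    variables: Sequence[str],
    group_cols: Sequence[str] = ("basin", "year"),
    min_length: int = 4,
) -> pd.DataFrame:
    """Lag-1 autocorrelation of each variable within each basin-year.

    Events are assumed time-ordered within each group.  A series is
    flagged when |r1| exceeds the approximate 95% white-noise band
    2/sqrt(n).  Series shorter than ``min_length`` or with zero variance
    are reported as not computable.
    """
    rows = []
    for keys, grp in data.groupby(list(group_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for v in variables:
            series = grp[v].to_numpy(dtype=float)
            n = series.size
            row = dict(zip(group_cols, keys))
            row["variable"] = v
            row["n"] = n
            if n < min_length or np.std(series) == 0:
                row.update(lag1_r=np.nan, flagged=False, computable=False)
            else:
                x0, x1 = series[:-1], series[1:]
                denom = np.std(x0) * np.std(x1)
                if denom == 0:
                    row.update(lag1_r=np.nan, flagged=False, computable=False)
                else:
                    r1 = float(np.mean((x0 - x0.mean()) * (x1 - x1.mean())) / denom)
                    row.update(lag1_r=r1, flagged=bool(abs(r1) > 2.0 / np.sqrt(n)), computable=True)
            rows.append(row)
    return pd.DataFrame(rows)
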