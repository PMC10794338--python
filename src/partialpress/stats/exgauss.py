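"""Maximum-likelihood ex-Gaussian reaction-time models.

The ex-Gaussian — a Gaussian (mu, sigma) convolved with an exponential of
mean beta — is the standard descriptive model for positively skewed RT
distributions; its mean is mu + beta and its variance sigma^2 + beta^2.
Densities come from :data:`scipy.stats.exponnorm` (shape K = beta / sigma).

Three fitting structures are provided:

``cells``
    an independent (mu, sigma, beta) MLE per item_type x partial cell;
``regression``
    fixed effects of item type and partial-error status: mu carries their
    interaction, log sigma and log beta carry the main effects (log links
    keep both positive);
``hierarchical``
    the regression plus Gaussian random intercepts on mu for participant and
    stimulus category, estimated by penalized (MAP) likelihood with the
    random-effect standard deviations profiled jointly.  This is a
    likelihood-based analogue of the full Bayesian mixed model, not a
    posterior simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["ExGaussParams", "ExGaussFit", "exgauss_logpdf", "fit_exgaussian",
           "fit_exgaussian_cell"]

_MIN_CELL_N = 50


def exgauss_logpdf(x, mu_ms: float, sigma_ms: float, beta_ms: float):
    """Log density of the ex-Gaussian at ``x`` (scipy exponnorm parameterization)."""
    if sigma_ms <= 0 or beta_ms <= 0:
        raise ValueError("sigma_ms and beta_ms must be positive")
    return stats.exponnorm.logpdf(x, beta_ms / sigma_ms, loc=mu_ms, scale=sigma_ms)


@dataclass
class ExGaussParams:
    """One cell's ex-Gaussian MLE with standard errors from the observed information."""

    mu_ms: float
    sigma_ms: float
    beta_ms: float
    n: int = 0
    loglik: float = math.nan
    converged: bool = True
    se: dict[str, float] = field(default_factory=dict)

    @property
    def mean_ms(self) -> float:
        """Implied mean RT, mu + beta."""
        return self.mu_ms + self.beta_ms

    @property
    def var_ms2(self) -> float:
        """Implied RT variance, sigma^2 + beta^2."""
        return self.sigma_ms**2 + self.beta_ms**2

    def density_integral(self) -> float:
        """Numerical check that the density integrates to 1."""
        from scipy import integrate

        val, _ = integrate.quad(
            lambda x: math.exp(exgauss_logpdf(x, self.mu_ms, self.sigma_ms, self.beta_ms)),
            self.mu_ms - 12 * self.sigma_ms,
            self.mu_ms + 12 * self.sigma_ms + 40 * self.beta_ms,
            limit=200,
        )
        return val


def _moment_start(x: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    skew = float(stats.skew(x, bias=False)) if x.size > 2 else 0.5
    beta0 = s * (max(skew, 0.05) / 2.0) ** (1.0 / 3.0)
    beta0 = min(max(beta0, 0.05 * s), 2.0 * s)
    sigma0 = math.sqrt(max(s * s - beta0 * beta0, (0.1 * s) ** 2))
    return m - beta0, sigma0, beta0


def _hessian_se(nll, theta: np.ndarray) -> dict[str, float]:
    """Standard errors from a central-difference Hessian of the NLL."""
    k = theta.size
    h = np.maximum(1e-4 * np.abs(theta), 1e-5)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        if not np.all(np.isfinite(ses)) or np.any(ses == 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return {}
    return dict(zip(("mu_ms", "sigma_ms", "beta_ms"), ses.tolist()))


def fit_exgaussian_cell(rts: Sequence[float], min_n: int = _MIN_CELL_N) -> ExGaussParams:
    """MLE of a single ex-Gaussian cell.

    Optimizes (mu, log sigma, log beta) from moment-based starting values;
    degenerate input (all RTs equal) yields a flagged, non-converged result
    rather than an exception.
    """
    x = np.asarray(rts, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D vector of at least 3 RTs")
    if np.any(x <= 0):
        raise ValueError("RTs must be positive")
    if x.size < min_n:
        raise ValueError(
            f"cell has {x.size} RTs; at least {min_n} required (pass min_n to override)"
        )
    if np.ptp(x) == 0:
        return ExGaussParams(float(x[0]), math.nan, math.nan, n=x.size,
                             converged=False)

    mu0, sigma0, beta0 = _moment_start(x)

    def nll_t(theta: np.ndarray) -> float:
        mu, log_s, log_b = theta
        return -float(np.sum(exgauss_logpdf(x, mu, math.exp(log_s), math.exp(log_b))))

    res = optimize.minimize(
        nll_t,
        np.array([mu0, math.log(sigma0), math.log(beta0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
    )
    mu, sigma, beta = res.x[0], math.exp(res.x[1]), math.exp(res.x[2])

    def nll_nat(theta: np.ndarray) -> float:
        if theta[1] <= 0 or theta[2] <= 0:
            return math.inf
        return -float(np.sum(exgauss_logpdf(x, theta[0], theta[1], theta[2])))

    se = _hessian_se(nll_nat, np.array([mu, sigma, beta])) if res.success else {}
    return ExGaussParams(
        float(mu), float(sigma), float(beta),
        n=int(x.size), loglik=-float(res.fun),
        converged=bool(res.success) and bool(se), se=se,
    )


@dataclass
class ExGaussFit:
    """Result of :func:`fit_exgaussian`: cell estimates and/or coefficients."""

    structure: str
    cells: dict[tuple, ExGaussParams] = field(default_factory=dict)
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    random_sd: dict[str, float] = field(default_factory=dict)
    loglik: float = math.nan
    converged: bool = True
    n: int = 0

    def cell_mean_ms(self, cell: tuple) -> float:
        return self.cells[cell].mean_ms


def _design(df: pd.DataFrame, cols: Sequence[str], interaction: bool) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept (and optional interaction)."""
    n = len(df)
    mats = [np.ones((n, 1))]
    names = ["intercept"]
    level_dummies: list[tuple[str, np.ndarray, list[str]]] = []
    for col in cols:
        levels = sorted(df[col].astype(str).unique())
        dm = np.column_stack(
            [(df[col].astype(str) == lvl).to_numpy(float) for lvl in levels[1:]]
        ) if len(levels) > 1 else np.empty((n, 0))
        level_dummies.append((col, dm, [f"{col}[{l}]" for l in levels[1:]]))
        mats.append(dm)
        names.extend(f"{col}[{l}]" for l in levels[1:])
    if interaction and len(level_dummies) == 2:
        (ca, da, na), (cb, dbm, nb) = level_dummies
        for i, ni in enumerate(na):
            for j, nj in enumerate(nb):
                mats.append((da[:, i] * dbm[:, j])[:, None])
                names.append(f"{ni}:{nj}")
    return np.hstack(mats), names


def fit_exgaussian(
    data: pd.DataFrame,
    structure: str = "cells",
    rt_col: str = "rt_ms",
    factors: Sequence[str] = ("item_type", "is_partial_error"),
    group_cols: Sequence[str] = ("participant_id", "category"),
    min_n: int = _MIN_CELL_N,
) -> ExGaussFit:
    """Fit ex-Gaussian RT models of increasing structure.

    ``cells`` fits each factor-combination independently (cells below
    ``min_n`` RTs are skipped and flag the fit); ``regression`` ties cells
    together through fixed effects (mu ~ factors + interaction, log sigma and
    log beta ~ main effects); ``hierarchical`` adds penalized Gaussian random
    intercepts on mu for each column of ``group_cols`` present in the data.
    Non-convergence is always flagged on the result, never silent.
    """
    if rt_col not in data.columns:
        raise ValueError(f"data lacks RT column {rt_col!r}")
    rts = data[rt_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(rts)) or np.any(rts <= 0):
        raise ValueError("RTs must be finite and positive")
    factors = [f for f in factors if f in data.columns]
    if structure == "cells":
        fit = ExGaussFit(structure="cells", n=len(data))
        ok = True
        total_ll = 0.0
        groups = data.groupby(list(factors)) if factors else [((), data)]
        for key, sub in groups:
            key = key if isinstance(key, tuple) else (key,)
            if len(sub) < min_n:
                ok = False
                continue
            cell = fit_exgaussian_cell(sub[rt_col].to_numpy(float), min_n=min_n)
            fit.cells[key] = cell
            ok &= cell.converged
            total_ll += cell.loglik
        fit.loglik = total_ll
        fit.converged = ok and bool(fit.cells)
        return fit

    if structure not in ("regression", "hierarchical"):
        raise ValueError(f"unknown structure {structure!r}")

    x_mu, names_mu = _design(data, factors, interaction=True)
    x_disp, names_disp = _design(data, factors, interaction=False)
    k_mu, k_disp = x_mu.shape[1], x_disp.shape[1]

    groups: list[tuple[str, np.ndarray, int]] = []
    if structure == "hierarchical":
        for col in group_cols:
            if col not in data.columns:
                continue
            levels = sorted(data[col].astype(str).unique())
            if len(levels) < 2:
                continue
            codes = data[col].astype(str).map(
                {l: i for i, l in enumerate(levels)}
            ).to_numpy()
            groups.append((col, codes, len(levels)))

    mu0, sigma0, beta0 = _moment_start(rts)
    theta0 = np.concatenate(
        [
            [mu0], np.zeros(k_mu - 1),
            [math.log(sigma0)], np.zeros(k_disp - 1),
            [math.log(beta0)], np.zeros(k_disp - 1),
            np.zeros(sum(g[2] for g in groups)),  # random intercepts
            np.full(len(groups), math.log(max(0.1 * sigma0, 1.0))),  # log sds
        ]
    )

    n_rand = sum(g[2] for g in groups)

    def unpack(theta):
        i = 0
        b_mu = theta[i : i + k_mu]; i += k_mu
        b_s = theta[i : i + k_disp]; i += k_disp
        b_b = theta[i : i + k_disp]; i += k_disp
        offsets = []
        for _, _, nl in groups:
            offsets.append(theta[i : i + nl]); i += nl
        log_sds = theta[i : i + len(groups)]
        return b_mu, b_s, b_b, offsets, log_sds

    def nll(theta: np.ndarray) -> float:
        b_mu, b_s, b_b, offsets, log_sds = unpack(theta)
        mu = x_mu @ b_mu
        for (_, codes, _), off in zip(groups, offsets):
            mu = mu + off[codes]
        log_s = np.clip(x_disp @ b_s, -10, 12)
        log_b = np.clip(x_disp @ b_b, -10, 12)
        sigma = np.exp(log_s)
        beta = np.exp(log_b)
        ll = np.sum(
            stats.exponnorm.logpdf(rts, beta / sigma, loc=mu, scale=sigma)
        )
        if not np.isfinite(ll):
            return 1e12
        penalty = 0.0
        for (_, _, nl), off, lsd in zip(groups, offsets, log_sds):
            sd = math.exp(np.clip(lsd, -10, 12))
            # Gaussian prior on the offsets, normalizer included so the sds
            # are identified (MAP / penalized likelihood)
            penalty += 0.5 * np.sum(off**2) / sd**2 + nl * math.log(sd)
        return -float(ll) + penalty

    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": 2000, "maxfun": 200_000})
    b_mu, b_s, b_b, offsets, log_sds = unpack(res.x)
    fit = ExGaussFit(
        structure=structure,
        coefficients={
            "mu_ms": dict(zip(names_mu, b_mu.tolist())),
            "log_sigma": dict(zip(names_disp, b_s.tolist())),
            "log_beta": dict(zip(names_disp, b_b.tolist())),
        },
        random_sd={
            col: math.exp(float(lsd)) for (col, _, _), lsd in zip(groups, log_sds)
        },
        loglik=-float(res.fun),
        converged=bool(res.success),
        n=len(data),
    )
    # per-cell fitted parameters for convenience (fixed effects only)
    if factors:
        cells = data[list(factors)].drop_duplicates()
        for _, row in cells.iterrows():
            mask = np.ones(len(data), dtype=bool)
            for f in factors:
                mask &= (data[f] == row[f]).to_numpy()
            i = int(np.flatnonzero(mask)[0])
            mu = float(x_mu[i] @ b_mu)
            sigma = float(np.exp(x_disp[i] @ b_s))
            beta = float(np.exp(x_disp[i] @ b_b))
            fit.cells[tuple(row[f] for f in factors)] = ExGaussParams(
                mu, sigma, beta, n=int(mask.sum()), converged=bool(res.success)
            )
    return fit
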