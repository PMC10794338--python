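"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity through a different route than the package:
trial outcomes by linear scan of densely sampled (1 kHz) trajectories, the
JZS t-test Bayes factor through the g-space integral (rather than the
effect-size-space integral the implementation uses), and the mixed-ANOVA
marginal likelihoods by deterministic tensor-grid quadrature over log g
(rather than Monte-Carlo sampling from the g prior).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats


# -- detection-rule oracle on the densified grid ---------------------------

def brute_force_outcome(record, threshold: float = 0.95, window_ms: float = 5.0):
    """Evaluate the threshold rules on 1 ms densified trajectories.

    Returns (rt_ms, pressed_key, starts_pressed, partial) where partial is
    None when there is no response.
    """
    keys = sorted(record.trajectories)
    dense = {}
    for k in keys:
        t, v = record.trajectories[k].densify(1000.0)
        dense[k] = (t, v)
    starts = False
    for k in keys:
        t, v = dense[k]
        if np.any(v[t <= window_ms] > 0):
            starts = True
    rt = None
    pressed = None
    best = {}
    for k in keys:
        t, v = dense[k]
        above = np.flatnonzero(v > threshold)
        if above.size:
            best[k] = t[above[0]]
    if best:
        rt = min(best.values())
        winners = [k for k, tv in best.items() if tv == rt]
        if len(winners) == 1:
            pressed = winners[0]
        else:
            vals = {k: dense[k][1][int(rt)] for k in winners}
            vmax = max(vals.values())
            top = sorted(k for k, v in vals.items() if v == vmax)
            pressed = top[0]
    partial = None
    if rt is not None:
        partial = all(
            bool(np.any(dense[k][1][dense[k][0] < rt] > 0)) for k in keys
        )
    return rt, pressed, starts, partial


# -- JZS t-test Bayes factor via the g-space integral ----------------------

def ttest_bf10_oracle(t: float, n: int, prior_scale: float = 0.707) -> float:
    """Two-sided JZS BF10 as the classic integral over g ~ InvGamma(1/2, r^2/2)."""
    df = n - 1
    r2 = prior_scale * prior_scale

    def integrand(g: float) -> float:
        return (
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * df)) ** (-(df + 1) / 2)
            * math.sqrt(r2 / 2) / math.gamma(0.5)
            * g ** -1.5
            * math.exp(-r2 / (2 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    den = (1 + t * t / df) ** (-(df + 1) / 2)
    return num / den


def ttest_bf10_grid_oracle(
    t: float, n: int, prior_scale: float = 0.707, direction: str = "two_sided"
) -> float:
    """Directional JZS BF10 by dense trapezoid integration over the effect size."""
    df = n - 1
    delta = np.linspace(-40, 40, 400_001)
    dens = stats.nct.pdf(t, df, delta * math.sqrt(n)) * stats.cauchy.pdf(
        delta, scale=prior_scale
    )
    if direction == "greater":
        mask = delta >= 0
        m1 = 2 * np.trapezoid(dens[mask], delta[mask])
    elif direction == "less":
        mask = delta <= 0
        m1 = 2 * np.trapezoid(dens[mask], delta[mask])
    else:
        m1 = np.trapezoid(dens, delta)
    return float(m1 / stats.t.pdf(t, df))


# -- mixed-ANOVA marginal likelihood by tensor-grid quadrature -------------

def _log_conditional(y, ones, batches, g):
    """log p(y | g) up to the model-independent constant, scalar route."""
    n = y.size
    sigma = np.eye(n)
    for (x, _), gj in zip(batches, g):
        sigma = sigma + gj * (x @ x.T)
    sign, logdet = np.linalg.slogdet(sigma)
    inv = np.linalg.inv(sigma)
    ot1 = ones @ inv @ ones
    oty = ones @ inv @ y
    q = y @ inv @ y - oty * oty / ot1
    return -0.5 * logdet - 0.5 * math.log(ot1) - 0.5 * (n - 1) * math.log(q)


def anova_log_marginal_qmc_oracle(y, batches, m: int = 17, qmc_seed: int = 20_101):
    """High-effort log marginal over g via scrambled-Sobol quasi-Monte Carlo.

    Maps a 2^m-point Sobol sequence through the inverse CDF of each g's
    inverse-gamma(1/2, r^2/2) prior and averages the conditional marginals,
    computed here by explicit matrix inverse and slogdet — an integration
    route independent of the package's pseudo-random prior sampling.
    Validated against tensor-grid Simpson quadrature in log g (below) on
    low-dimensional models.
    """
    from scipy.stats import qmc

    y = np.asarray(y, dtype=float)
    n = y.size
    ones = np.ones(n)
    if not batches:
        q = y @ y - (ones @ y) ** 2 / n
        return -0.5 * math.log(n) - 0.5 * (n - 1) * math.log(q)
    k = len(batches)
    sob = qmc.Sobol(d=k, scramble=True, seed=qmc_seed)
    u = sob.random_base2(m)
    g = np.column_stack(
        [
            stats.invgamma.ppf(u[:, j], 0.5, scale=r * r / 2)
            for j, (_, r) in enumerate(batches)
        ]
    )
    grams = [x @ x.T for x, _ in batches]
    rhs = np.column_stack([y, ones])
    out = np.empty(len(g))
    for s in range(0, len(g), 65536):
        gg = g[s : s + 65536]
        b = len(gg)
        sigma = np.broadcast_to(np.eye(n), (b, n, n)).copy()
        for j, gram in enumerate(grams):
            sigma += gg[:, j, None, None] * gram
        _, logdet = np.linalg.slogdet(sigma)
        inv = np.linalg.inv(sigma)
        z = inv @ rhs
        yty = np.einsum("i,bi->b", y, z[:, :, 0])
        ot1 = np.einsum("i,bi->b", ones, z[:, :, 1])
        oty = np.einsum("i,bi->b", ones, z[:, :, 0])
        q = yty - oty**2 / ot1
        out[s : s + b] = -0.5 * logdet - 0.5 * np.log(ot1) - 0.5 * (n - 1) * np.log(q)
    mx = out.max()
    return mx + math.log(float(np.exp(out - mx).mean()))


def anova_log_marginal_simpson_oracle(y, batches, nodes: int = 65,
                                      u_lo=-16.0, u_hi=20.0):
    """Deterministic log marginal over g via Simpson quadrature in u = log g.

    ``batches`` is a list of (design matrix, Cauchy scale r); each g_b has an
    inverse-gamma(1/2, r_b^2/2) prior.  Independent of the package's
    Monte-Carlo route.  Up to the same model-independent constant as the
    package's ``_log_marginal_mc``.  Scalar evaluation: use only for models
    with at most ~3 g dimensions.
    """
    y = np.asarray(y, dtype=float)
    ones = np.ones(y.size)
    if not batches:
        q = y @ y - (ones @ y) ** 2 / y.size
        return -0.5 * math.log(y.size) - 0.5 * (y.size - 1) * math.log(q)
    u = np.linspace(u_lo, u_hi, nodes)
    k = len(batches)
    # log prior density of g at exp(u), times the Jacobian exp(u)
    logprior = []
    for _, r in batches:
        g = np.exp(u)
        lp = (
            0.5 * math.log(r * r / 2)
            - math.lgamma(0.5)
            - 1.5 * u
            - (r * r) / (2 * g)
            + u  # Jacobian dg = e^u du
        )
        logprior.append(lp)
    vals = np.empty([nodes] * k)
    for idx in itertools.product(range(nodes), repeat=k):
        g = [math.exp(u[i]) for i in idx]
        lp = _log_conditional(y, ones, batches, g)
        vals[idx] = lp + sum(logprior[j][i] for j, i in enumerate(idx))
    m = vals.max()
    w = np.exp(vals - m)
    for _ in range(k):
        w = integrate.simpson(w, x=u, axis=-1)
    return m + math.log(float(w))


def anova_batches(df, dv, within_levels, between="condition",
                  prior_scale=0.5, random_scale=1.0):
    """Build the model design batches exactly as the implementation defines them."""
    from partialpress.stats.bayesfactor import (
        _factor_columns,
        _interaction_columns,
    )

    df = df[df["item_type"].isin(within_levels)]
    df = df.sort_values(["participant_id", "item_type"]).reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)
    participants = sorted(df["participant_id"].unique())
    p_codes = df["participant_id"].map(
        {p: i for i, p in enumerate(participants)}
    ).to_numpy()
    conditions = sorted(df[between].unique())
    c_codes = df[between].map({c: i for i, c in enumerate(conditions)}).to_numpy()
    levels = sorted(within_levels)
    w_codes = df["item_type"].map({l: i for i, l in enumerate(levels)}).to_numpy()
    z = np.zeros((len(df), len(participants)))
    z[np.arange(len(df)), p_codes] = 1.0
    xb = _factor_columns(c_codes, len(conditions))
    xw = _factor_columns(w_codes, len(levels))
    xi = _interaction_columns(c_codes, len(conditions), w_codes, len(levels))
    models = {
        "Null": [(z, random_scale)],
        "Fam": [(z, random_scale), (xb, prior_scale)],
        "Main": [(z, random_scale), (xb, prior_scale), (xw, prior_scale)],
        "Full": [(z, random_scale), (xb, prior_scale), (xw, prior_scale),
                 (xi, prior_scale)],
    }
    return y, models


# -- ex-Gaussian moment identities ----------------------------------------

def exgauss_moments(mu, sigma, beta):
    """Mean and variance implied by ex-Gaussian parameters."""
    return mu + beta, sigma * sigma + beta * beta
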