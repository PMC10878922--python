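"""Bayesian inference: gamma priors, random-walk Metropolis–Hastings, HPD, Geweke.

The four parameters get independent Gamma(a_i, b_i) priors (shape/rate).
Proposals are independent Gaussian steps on log-parameters, so positivity is
automatic; the acceptance ratio therefore includes the log-scale Jacobian
``prod_j p_j``.  Per-parameter proposal scales are adapted during burn-in
toward a 20–40% acceptance rate and then frozen, keeping the post-burn-in
chain a valid Metropolis sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mle
from .params import ParameterVector

__all__ = [
    "PriorSpec",
    "PosteriorChain",
    "log_prior",
    "log_posterior",
    "mh_sampler",
    "hpd_interval",
    "geweke_z",
    "posterior_summary",
]

PARAM_NAMES = ("theta", "beta", "lam", "alpha")


@dataclass(frozen=True)
class PriorSpec:
    """Gamma shape/rate pairs for (alpha, beta, theta, lam).

    Defaults ``a_i = b_i = 0.1`` are vague but proper.
    """

    a_alpha: float = 0.1
    b_alpha: float = 0.1
    a_beta: float = 0.1
    b_beta: float = 0.1
    a_theta: float = 0.1
    b_theta: float = 0.1
    a_lam: float = 0.1
    b_lam: float = 0.1

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"hyperparameter {f} must be positive")

    def pairs(self) -> dict:
        return {
            "theta": (self.a_theta, self.b_theta),
            "beta": (self.a_beta, self.b_beta),
            "lam": (self.a_lam, self.b_lam),
            "alpha": (self.a_alpha, self.b_alpha),
        }


def log_prior(p: ParameterVector, prior: PriorSpec) -> float:
    """Sum of gamma log-densities up to additive constants; -inf off-support."""
    total = 0.0
    pairs = prior.pairs()
    for name in PARAM_NAMES:
        v = getattr(p, name if name != "lam" else "lam")
        a, b = pairs[name]
        if v <= 0 or not np.isfinite(v):
            return -math.inf
        total += (a - 1.0) * math.log(v) - b * v
    return total


def log_posterior(p: ParameterVector, sample, prior: PriorSpec) -> float:
    """``log_prior + log_likelihood`` (proportionality constant omitted)."""
    lp = log_prior(p, prior)
    if not np.isfinite(lp):
        return -math.inf
    try:
        with np.errstate(all="ignore"):
            ll = -mle.nll(p, sample)
    except Exception:
        return -math.inf
    return lp + ll if np.isfinite(ll) else -math.inf


@dataclass
class PosteriorChain:
    """Kept (post burn-in, thinned) draws with sampler metadata."""

    draws: np.ndarray  # (kept, 4) in order (theta, beta, lam, alpha)
    n_iter: int
    burn_in: int
    thin: int
    acceptance_rate: float
    seed: int
    proposal_scale: np.ndarray
    warning: str = ""

    @property
    def param_names(self) -> tuple:
        return PARAM_NAMES


def mh_sampler(
    sample,
    prior: PriorSpec | None = None,
    n_iter: int = 50_000,
    burn_in: int = 5_000,
    thin: int = 10,
    seed: int = 0,
    proposal_scale: float | np.ndarray = 0.1,
    init: ParameterVector | None = None,
    log_target=None,
) -> PosteriorChain:
    """Random-walk Metropolis–Hastings on log-parameters.

    ``log_target(ParameterVector) -> float`` may replace the default
    posterior (used by the conjugate-oracle tests).  Deterministic under
    ``seed``: identical seeds reproduce draws bit-for-bit.
    """
    if burn_in >= n_iter:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    prior = prior or PriorSpec()
    if log_target is None:
        x = np.asarray(sample, dtype=float)

        def log_target(p):
            return log_posterior(p, x, prior)

    rng = np.random.default_rng(seed)
    cur = (init or ParameterVector(theta=1.0, beta=1.0, lam=1.0, alpha=1.0)).as_array()
    logcur = log_target(ParameterVector.from_array(cur))
    if not np.isfinite(logcur):
        raise ValueError("initial state has zero posterior density")
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), (4,)).copy()

    kept = []
    accepted_post = 0
    proposed_post = 0
    window_acc = 0
    window_n = 0
    y = np.log(cur)
    logjac = y.sum()  # log prod p_j
    for it in range(n_iter):
        step = rng.normal(0.0, 1.0, 4) * scale
        y_new = y + step
        p_new = np.exp(y_new)
        lt = log_target(ParameterVector.from_array(p_new))
        log_ratio = (lt + y_new.sum()) - (logcur + logjac)
        accepted = math.log(rng.random()) < log_ratio
        if accepted:
            y, logcur, logjac = y_new, lt, y_new.sum()
        if it < burn_in:
            window_acc += accepted
            window_n += 1
            if window_n == 100:  # adapt toward 20-40% acceptance
                rate = window_acc / window_n
                if rate < 0.20:
                    scale *= 0.8
                elif rate > 0.40:
                    scale *= 1.25
                window_acc = window_n = 0
        else:
            proposed_post += 1
            accepted_post += accepted
            if (it - burn_in) % thin == 0:
                kept.append(np.exp(y))
    draws = np.array(kept)
    acc_rate = accepted_post / max(proposed_post, 1)
    warning = ""
    if not (0.05 < acc_rate < 0.7):
        warning = f"acceptance rate {acc_rate:.3f} outside (0.05, 0.7) after adaptation"
    return PosteriorChain(
        draws=draws,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        acceptance_rate=acc_rate,
        seed=seed,
        proposal_scale=scale,
        warning=warning,
    )


def hpd_interval(draws, mass: float = 0.95):
    """Shortest window containing ``ceil(mass*N)`` sorted draws."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    if not (0 < mass <= 1):
        raise ValueError("mass must lie in (0, 1]")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(d[0]), float(d[-1])
    widths = d[m - 1:] - d[: n - m + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m - 1])


def _spectral_var_at_zero(x: np.ndarray) -> float:
    """Spectral density of the mean at frequency zero via a Bartlett lag window."""
    n = x.size
    xc = x - x.mean()
    max_lag = min(n - 1, max(1, int(round(n**0.5))))
    var = float(np.mean(xc * xc))
    s = var
    for lag in range(1, max_lag + 1):
        gamma = float(np.mean(xc[:-lag] * xc[lag:]))
        s += 2.0 * (1.0 - lag / (max_lag + 1.0)) * gamma
    return max(s, 0.0)


def geweke_z(draws, frac_a: float = 0.1, frac_b: float = 0.5):
    """Geweke convergence z-score between early and late chain windows.

    Compares the mean of the first ``frac_a`` fraction with the last
    ``frac_b`` fraction; the standard error uses the spectral density at
    zero of each window, so the score is ~N(0,1) for a stationary chain.
    Degenerate (constant) chains return ``(0.0, flagged=True)``.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    na, nb = int(frac_a * n), int(frac_b * n)
    if na + nb > n:
        raise ValueError("windows overlap: frac_a + frac_b must be <= 1")
    if na < 2 or nb < 2:
        raise ValueError("windows too small")
    if np.ptp(x) == 0.0:  # constant chain: 0/0 guarded
        return 0.0, True
    a, b = x[:na], x[n - nb:]
    va = _spectral_var_at_zero(a) / na
    vb = _spectral_var_at_zero(b) / nb
    denom = math.sqrt(va + vb)
    if denom == 0.0:
        return 0.0, True
    return float((a.mean() - b.mean()) / denom), False


def posterior_summary(chain: PosteriorChain, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD, HPD bounds and Geweke score per parameter."""
    rows = []
    for j, name in enumerate(chain.param_names):
        d = chain.draws[:, j]
        lo, hi = hpd_interval(d, mass) if d.size >= 100 else (float(d.min()), float(d.max()))
        if np.ptp(d) == 0.0:
            lo = hi = float(d[0])
            z = 0.0
        else:
            z, _ = geweke_z(d)
        rows.append({
            "Estimates": float(d.mean()),
            "SD": float(d.std(ddof=1)) if d.size > 1 else 0.0,
            "Lower": lo,
            "Upper": hi,
            "Geweke's z-score": z,
        })
    return pd.DataFrame(rows, index=list(chain.param_names))


def trace_plot_data(chain: PosteriorChain) -> pd.DataFrame:
    """Kept draws indexed by iteration — plot-ready trace coordinates."""
    df = pd.DataFrame(chain.draws, columns=list(chain.param_names))
    df.insert(0, "iteration", chain.burn_in + chain.thin * np.arange(len(df)))
    return df


def density_plot_data(chain: PosteriorChain, bins: int = 50) -> dict:
    """Histogram-density coordinates per parameter."""
    out = {}
    for j, name in enumerate(chain.param_names):
        hist, edges = np.histogram(chain.draws[:, j], bins=bins, density=True)
        out[name] = pd.DataFrame({"x": 0.5 * (edges[1:] + edges[:-1]), "density": hist})
    return out
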