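import math

import numpy as np
import pytest

from naptplx import ParameterVector, load_bundled


@pytest.fixture(scope="session")
def bladder():
    """Remission times (months) of 128 bladder-cancer patients."""
    return load_bundled("bladder").values


@pytest.fixture(scope="session")
def income():
    """59 monthly Egyptian income-tax observations."""
    return load_bundled("income_tax").values


@pytest.fixture(scope="session")
def p_std():
    """Reference parameter set with all moments up to order 4 finite."""
    return ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240205)


def integrate_pdf(p, pdf=None):
    """Quadrature of the density over (0, inf), split at quantiles.

    Heavy-tail configurations (theta*beta near zero) spread mass over many
    orders of magnitude; quantile-guided breakpoints keep the adaptive rule
    honest.  A wrong quantile function can only misplace breakpoints and make
    the check fail, never pass it spuriously.
    """
    from scipy import integrate

    import naptplx as nx

    pdf = pdf or (lambda t: nx.pdf(t, p))
    probs = [0.05, 0.25, 0.5, 0.75, 0.9, 0.99, 0.999, 1 - 1e-5, 1 - 1e-8, 1 - 1e-11]
    cuts = [nx.quantile(u, p) for u in probs]
    total, _ = integrate.quad(pdf, 0.0, cuts[0], limit=200)
    # beyond the 5% point integrate in log-x: power-law tails spanning many
    # decades become exponentially decaying integrands there
    def g(u):
        if u > 700.0:  # pdf underflows long before exp(u) overflows
            return 0.0
        return pdf(math.exp(u)) * math.exp(u)
    logs = [math.log(c) for c in cuts]
    for a, b in zip(logs[:-1], logs[1:]):
        v, _ = integrate.quad(g, a, b, limit=200)
        total += v
    v, _ = integrate.quad(g, logs[-1], np.inf, limit=200)
    return total + v


def random_valid_params(rng, n):
    """Log-uniform parameter draws inside the strict validity region."""
    out = []
    while len(out) < n:
        th, be, lam = np.exp(rng.uniform(np.log(0.3), np.log(5.0), 3))
        al = np.exp(rng.uniform(np.log(0.4), np.log(50.0)))
        out.append(ParameterVector(theta=th, beta=be, lam=lam, alpha=al))
    return out
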