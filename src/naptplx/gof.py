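"""Goodness-of-fit battery and model comparison.

Classical EDF statistics against a fully specified cdf:

* KS:  ``D = max_i max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n)``
* AD:  ``A² = -n - (1/n) sum_i (2i-1) [log F(x_(i)) + log(1 - F(x_(n+1-i)))]``
* CVM: ``W² = 1/(12n) + sum_i (F(x_(i)) - (2i-1)/(2n))²``

P-values use the standard asymptotic null distributions and are approximate
when the cdf's parameters were estimated from the same sample (the usual
convention in distribution-fitting comparisons; reported as-is, flagged in
the column name).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import competitors

__all__ = [
    "aic",
    "bic",
    "ks_statistic",
    "ad_statistic",
    "cvm_statistic",
    "GoodnessOfFitReport",
    "comparison_table",
    "ttt_plot_data",
    "boxplot_stats",
    "pp_plot_data",
    "fitted_curve_data",
]

_CLIP = 1e-12


def aic(nll: float, k: int) -> float:
    """Akaike information criterion ``2k + 2*nll``."""
    return 2.0 * k + 2.0 * nll


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian information criterion ``k*log(n) + 2*nll``."""
    return k * math.log(n) + 2.0 * nll


def _sorted_probs(sample, cdf_callable):
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    return x, np.asarray(cdf_callable(x), dtype=float)


def ks_statistic(sample, cdf_callable):
    """Two-sided Kolmogorov–Smirnov statistic and asymptotic p-value."""
    x, F = _sorted_probs(sample, cdf_callable)
    n = x.size
    i = np.arange(1, n + 1)
    D = float(max(np.max(i / n - F), np.max(F - (i - 1) / n)))
    pvalue = float(stats.kstwo.sf(D, n))
    return D, pvalue


def _ad_pvalue(a2: float) -> float:
    """Asymptotic upper tail of the Anderson–Darling null distribution.

    Standard piecewise approximation (D'Agostino & Stephens style); adequate
    for reporting, not for sharp inference.
    """
    if a2 < 0.2:
        return 1.0 - math.exp(-13.436 + 101.14 * a2 - 223.73 * a2**2)
    if a2 < 0.34:
        return 1.0 - math.exp(-8.318 + 42.796 * a2 - 59.938 * a2**2)
    if a2 < 0.6:
        return math.exp(0.9177 - 4.279 * a2 - 1.38 * a2**2)
    return math.exp(1.2937 - 5.709 * a2 + 0.0186 * a2**2)


def ad_statistic(sample, cdf_callable, return_pvalue: bool = False):
    """Anderson–Darling statistic (and optionally its approximate p-value)."""
    x, F = _sorted_probs(sample, cdf_callable)
    n = x.size
    F = np.clip(F, _CLIP, 1.0 - _CLIP)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log(1.0 - F[::-1]))))
    if return_pvalue:
        return a2, _ad_pvalue(a2)
    return a2


def cvm_statistic(sample, cdf_callable, return_pvalue: bool = False):
    """Cramér–von Mises statistic (and optionally its asymptotic p-value)."""
    x, F = _sorted_probs(sample, cdf_callable)
    n = x.size
    F = np.clip(F, _CLIP, 1.0 - _CLIP)
    i = np.arange(1, n + 1)
    w2 = float(1.0 / (12.0 * n) + np.sum((F - (2 * i - 1) / (2.0 * n)) ** 2))
    if return_pvalue:
        res = stats.cramervonmises(np.asarray(sample, dtype=float), cdf_callable)
        return w2, float(res.pvalue)
    return w2


@dataclass
class GoodnessOfFitReport:
    """Per-model comparison rows plus rankings by each criterion."""

    label: str
    table: pd.DataFrame
    fits: dict

    def ranking(self, criterion: str = "nll") -> list:
        ok = self.table.dropna(subset=[criterion])
        return list(ok.sort_values(criterion).index)


def comparison_table(
    sample,
    model_names=("Lx", "PLx", "MOLx", "MOPLx", "NAPTPLx"),
    label: str = "sample",
    n_starts: int = 25,
    seed: int = 0,
) -> GoodnessOfFitReport:
    """Fit each model and assemble the comparison table.

    Columns mirror the classic layout: estimates, SEs, KS, AD, CVM, NLL,
    AIC, BIC.  A model whose fit fails contributes a flagged NaN row rather
    than being dropped.
    """
    if len(model_names) == 0:
        raise ValueError("at least one model required")
    x = np.asarray(sample, dtype=float)
    rows, fits = {}, {}
    for name in model_names:
        try:
            fr = competitors.fit_model(name, x, n_starts=n_starts, seed=seed)
            cdf = competitors.model_cdf_callable(name, fr.estimates)
            ks, ks_p = ks_statistic(x, cdf)
            ad = ad_statistic(x, cdf)
            cvm = cvm_statistic(x, cdf)
            rows[name] = {
                "estimates": fr.params_dict(),
                "ses": dict(zip(fr.param_names, fr.ses)) if fr.ses is not None else None,
                "ks": ks,
                "ks_pvalue_approx": ks_p,
                "ad": ad,
                "cvm": cvm,
                "nll": fr.nll,
                "aic": fr.aic,
                "bic": fr.bic,
                "error": "",
            }
            fits[name] = fr
        except Exception as exc:  # flagged, not dropped
            rows[name] = {
                "estimates": None, "ses": None, "ks": np.nan,
                "ks_pvalue_approx": np.nan, "ad": np.nan, "cvm": np.nan,
                "nll": np.nan, "aic": np.nan, "bic": np.nan, "error": str(exc),
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return GoodnessOfFitReport(label=label, table=table, fits=fits)


# ---------------------------------------------------------------------------
# plot-ready data


def ttt_plot_data(sample) -> np.ndarray:
    """Scaled total-time-on-test transform coordinates.

    Returns the (n+1)×2 array of points ``(i/n, T_i / T_n)`` with
    ``T_i = sum_{j<=i} x_(j) + (n-i) x_(i)``; starts at (0,0), ends at (1,1).
    Concave curves indicate increasing hazard, convex decreasing, and a
    concave-then-convex S-shape a unimodal (upside-down bathtub) hazard.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0):
        raise ValueError("TTT transform requires positive observations")
    cs = np.cumsum(x)
    i = np.arange(1, n + 1)
    T = cs + (n - i) * x
    pts = np.column_stack([i / n, T / cs[-1]])
    return np.vstack([[0.0, 0.0], pts])


def boxplot_stats(sample) -> dict:
    """Five-number summary plus 1.5·IQR outliers."""
    x = np.asarray(sample, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": np.sort(x[(x < lo_fence) | (x > hi_fence)]),
    }


def pp_plot_data(sample, cdf_callable) -> np.ndarray:
    """(empirical, fitted) probability pairs; ties share averaged ranks."""
    x = np.asarray(sample, dtype=float)
    n = x.size
    emp = stats.rankdata(x, method="average") / n
    order = np.argsort(x)
    return np.column_stack([emp[order], np.asarray(cdf_callable(x))[order]])


def fitted_curve_data(sample, name: str, params, grid=None) -> pd.DataFrame:
    """pdf/cdf/survival of a fitted model on a grid (plot-ready table)."""
    x = np.asarray(sample, dtype=float)
    if grid is None:
        grid = np.linspace(max(x.min() * 0.5, 1e-9), x.max() * 1.05, 200)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return pd.DataFrame(columns=["x", "pdf", "cdf", "survival"])
    pdfv = competitors.competitor_pdf(name, params, grid)
    cdfv = competitors.competitor_cdf(name, params, grid)
    return pd.DataFrame({"x": grid, "pdf": pdfv, "cdf": cdfv, "survival": 1.0 - cdfv})
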