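"""Gradient statistics: AIC model selection, Cohen's d, annual climate CV.

Relationships between species richness and the community indexes are
summarized by ordinary least squares, comparing a linear and a quadratic
polynomial and keeping the model with the lower Gaussian-likelihood AIC.
Between-region contrasts use Cohen's d with the conventional magnitude
labels, and climate seasonality is the multi-year mean of within-year
coefficients of variation of monthly values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["RegressionFit", "fit_best", "cohens_d", "climate_cv"]


@dataclass(frozen=True)
class RegressionFit:
    model: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]  # intercept first, then increasing power
    r2: float
    aic: float
    n: int
    selected: bool = False


def _ols(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[tuple, float, float]:
    X = sm.add_constant(np.column_stack([x**p for p in range(1, degree + 1)]))
    res = sm.OLS(y, X).fit()
    return tuple(res.params.tolist()), float(res.rsquared), float(res.aic)


def fit_best(x, y) -> tuple[RegressionFit, RegressionFit]:
    """Fit y ~ x and y ~ x + x^2 by OLS; select the lower-AIC model.

    AIC uses the Gaussian log-likelihood with estimated variance; only AIC
    differences matter for the selection, which is invariant to the additive
    likelihood constant. Returns (linear, quadratic) fits with the chosen one
    flagged ``selected``. Under an exact AIC tie the simpler (linear) model
    wins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]):
        raise ValueError("x is constant; regression undefined")
    coef_l, r2_l, aic_l = _ols(x, y, 1)
    coef_q, r2_q, aic_q = _ols(x, y, 2)
    lin_wins = aic_l <= aic_q
    return (
        RegressionFit("linear", coef_l, r2_l, aic_l, len(x), lin_wins),
        RegressionFit("quadratic", coef_q, r2_q, aic_q, len(x), not lin_wins),
    )


_D_LABELS = ((0.2, "N"), (0.5, "S"), (0.8, "M"))


def cohens_d(group1, group2) -> tuple[float, str]:
    """Standardized mean difference (pooled, n-1 sd) with a magnitude label.

    d = (mean1 - mean2) / s_pooled. Labels: N (negligible, |d| < 0.2),
    S (small, 0.2 <= |d| < 0.5), M (medium, 0.5 <= |d| < 0.8),
    L (large, |d| >= 0.8). The sign is preserved, so the direction of the
    contrast is readable from the value.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((g1.mean() - g2.mean()) / pooled)
    label = "L"
    for cut, lab in _D_LABELS:
        if abs(d) < cut:
            label = lab
            break
    return d, label


def climate_cv(monthly, years: int | None = None) -> float:
    """Mean over years of the within-year CV of 12 monthly values.

    ``monthly`` is a (years x 12) matrix (or a flat vector whose length is a
    multiple of 12). Per-year CV = sample sd / mean of that year's months;
    a year with zero mean is reported by index.
    """
    m = np.asarray(monthly, dtype=float)
    if m.ndim == 1:
        if m.size % 12:
            raise ValueError("flat monthly vector length must be a multiple of 12")
        m = m.reshape(-1, 12)
    if m.shape[1] != 12:
        raise ValueError("each year must have exactly 12 monthly values")
    if years is not None and m.shape[0] != years:
        raise ValueError(f"expected {years} years, got {m.shape[0]}")
    means = m.mean(axis=1)
    zero = means == 0
    if zero.any():
        raise ValueError(f"zero yearly mean in year(s): {np.nonzero(zero)[0].tolist()}")
    cvs = m.std(axis=1, ddof=1) / means
    return float(cvs.mean())
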