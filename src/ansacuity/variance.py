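"""Explained-variance indices and within-participant ANOVA.

Two per-participant indices quantify how much of a participant's trial-level
performance the numerosity ratio accounts for:

* ``r2_ols`` -- the ordinary coefficient of determination of RT regressed on
  ratio (linear model);
* ``r2_lr`` -- the likelihood-ratio (Cox-Snell) pseudo-R-squared of a
  logit binomial GLM of correctness on ratio,
  ``1 - exp((2/n) (l0 - l1))`` with ``l1`` the fitted and ``l0`` the
  intercept-only log-likelihood.  An optional Nagelkerke rescaling divides
  by the maximum attainable value ``1 - exp(2 l0 / n)``.

Condition effects on these per-participant indices are tested with a one-way
repeated-measures ANOVA, with a Greenhouse-Geisser sphericity correction of
the degrees of freedom, plus paired planned contrasts with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import bh_adjust
from .psychomodels import fit_probit_glm

__all__ = ["RmAnovaResult", "r2_ols", "r2_lr", "rm_anova_gg", "paired_contrasts"]


def r2_ols(trials: pd.DataFrame, predictor: str = "ratio_R") -> float:
    """Coefficient of determination of RT on the ratio (per participant)."""
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    y = trials["rt_ms"].to_numpy(dtype=float)
    if y.std() == 0:
        return 0.0
    x = trials[predictor].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.rsquared)


def r2_lr(
    trials: pd.DataFrame, predictor: str = "ratio_R", rescale: str | None = None
) -> float:
    """Likelihood-ratio pseudo-R-squared of correctness on the ratio.

    Fitted with a binomial GLM and logit link against the intercept-only
    null.  ``rescale="nagelkerke"`` divides by the maximum attainable value.
    Returns NaN when the fit separates or fails to converge.
    """
    y = trials["correct"].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 trials")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    x = trials[predictor].to_numpy(dtype=float)
    full = fit_probit_glm(y, x, has_intercept=True, link="logit")
    null = fit_probit_glm(y, np.zeros((n, 0)), has_intercept=True, link="logit")
    if not (full.converged and null.converged):
        return np.nan
    value = 1.0 - np.exp((2.0 / n) * (null.log_likelihood - full.log_likelihood))
    if rescale == "nagelkerke":
        value /= 1.0 - np.exp(2.0 * null.log_likelihood / n)
    return float(value)


@dataclass
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    epsilon_gg: float
    p_uncorrected: float
    p_gg: float


def rm_anova_gg(values: pd.DataFrame | np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``values`` is a complete participants x conditions matrix.  The F
    statistic has (k-1, (k-1)(n-1)) degrees of freedom; the Greenhouse-
    Geisser epsilon is computed from the double-centered within-participant
    covariance matrix and scales both df for the corrected p-value.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a 2-D participants x conditions matrix")
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 3:
        raise ValueError("need at least 3 participants")
    if not np.isfinite(X).all():
        raise ValueError("matrix must be complete (no missing cells)")

    grand = X.mean()
    cond_means = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    p_unc = float(stats.f.sf(F, df1, df2))

    # Greenhouse-Geisser epsilon from the double-centered covariance matrix
    S = np.cov(X, rowvar=False)
    D = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    eps = (np.trace(D) ** 2) / ((k - 1) * (D**2).sum())
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    return RmAnovaResult(
        F=float(F), df1=df1, df2=df2, epsilon_gg=eps, p_uncorrected=p_unc, p_gg=p_gg
    )


def paired_contrasts(
    values: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    adjust: str = "bh",
) -> pd.DataFrame:
    """Paired t-tests for planned condition contrasts.

    ``values`` is a participants x conditions DataFrame; ``pairs`` names
    column pairs.  Adjustment (default BH) is applied over the requested
    family.  Identical columns yield t = 0, p = 1.
    """
    rows = []
    for a, b in pairs:
        d = values[a].to_numpy(dtype=float) - values[b].to_numpy(dtype=float)
        n = len(d)
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(values[a], values[b])
        rows.append({"a": a, "b": b, "t": float(t), "df": n - 1, "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    else:
        out["p_adj"] = out["p_raw"]
    return out
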