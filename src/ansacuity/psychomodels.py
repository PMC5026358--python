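"""Generative accuracy models and Weber-fraction estimation.

Three parameterizations of approximate-number-system (ANS) acuity are
implemented, each expressing the probability of a correct two-alternative
numerosity comparison through a single width parameter, the Weber fraction w:

* **linear** (scalar-variability) model: tuning curves on a linear scale with
  width proportional to numerosity,

  ``p_correct(r, w) = Phi(|r - 1| / (w * sqrt(r**2 + 1)))``

  where r is the ratio of the two numerosities (either convention; the
  predictor is invariant under r <-> 1/r).

* **log** (log-Gaussian) model: fixed-width tuning curves on a log scale,

  ``p_choose_right(r_num, w) = 1/2 + 1/2 * erf(log2(r_num) / (2 w))``

  equivalently ``p_correct = Phi(|log2 r_num| / (sqrt(2) w))`` with
  r_num = n_right / n_left.

* **modlog**: the DeWind extension of the log model with an intercept
  (side bias) and visual-feature predictors,

  ``p_choose_right = Phi(b_side + b_num*log2 r_num + b_size*log2 r_size
  + b_spacing*log2 r_spacing)``, w = 1 / (sqrt(2) * b_num).

Each reduces to a probit regression: the linear and log models are
no-intercept probit fits of correctness on a single transformed predictor
(beta = 1/w and beta = 1/(sqrt(2) w) respectively); the modlog model is an
intercepted probit fit of the *chosen side* on signed predictors.

Participants whose fitted slope is not significantly positive are flagged for
exclusion (two-sided Wald test at alpha = .05, plus non-convergence or a
non-positive slope), which mirrors discarding negative and very large Weber
fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GlmFit",
    "WeberFit",
    "predict_accuracy_linear",
    "predict_choose_right_log",
    "predict_accuracy_log",
    "predict_choose_right_modlog",
    "weber_predictor_linear",
    "weber_predictor_log",
    "weber_predictor",
    "fit_probit_glm",
    "fit_weber",
    "lr_test_predictor",
]

ALPHA_EXCLUSION = 0.05
LARGE_W = 2.0
MAX_ABS_LINPRED = 30.0  # beyond this the fit is treated as separated
SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# prediction functions


def _check_w(w: float) -> None:
    if not np.all(np.asarray(w) > 0):
        raise ValueError("Weber fraction w must be positive")


def predict_accuracy_linear(r, w):
    """Probability of a correct response under the linear (scalar) model.

    ``r`` may be the larger/smaller ratio (>= 1) or the smaller/larger ratio
    in (0, 1); the prediction is identical for r and 1/r.
    """
    _check_w(w)
    r = np.asarray(r, dtype=float)
    return stats.norm.cdf(np.abs(r - 1.0) / (np.asarray(w) * np.sqrt(r**2 + 1.0)))


def predict_choose_right_log(r_num, w):
    """Probability of choosing the right set under the log-Gaussian model."""
    _check_w(w)
    r_num = np.asarray(r_num, dtype=float)
    from scipy.special import erf

    return 0.5 + 0.5 * erf(np.log2(r_num) / (2.0 * np.asarray(w)))


def predict_accuracy_log(r_num, w):
    """Probability of a correct response under the log-Gaussian model."""
    _check_w(w)
    r_num = np.asarray(r_num, dtype=float)
    return stats.norm.cdf(np.abs(np.log2(r_num)) / (SQRT2 * np.asarray(w)))


def predict_choose_right_modlog(
    r_num, log2_r_size, log2_r_spacing, beta_side, beta_num, beta_size, beta_spacing
):
    """Probability of choosing the right set under the DeWind modified model."""
    eta = (
        beta_side
        + beta_num * np.log2(np.asarray(r_num, dtype=float))
        + beta_size * np.asarray(log2_r_size, dtype=float)
        + beta_spacing * np.asarray(log2_r_spacing, dtype=float)
    )
    return stats.norm.cdf(eta)


# ---------------------------------------------------------------------------
# predictors


def weber_predictor_linear(ratio):
    """Linear-model probit predictor |r - 1| / sqrt(r**2 + 1).

    Invariant under r <-> 1/r, so either ratio convention may be passed.
    """
    r = np.asarray(ratio, dtype=float)
    return np.abs(r - 1.0) / np.sqrt(r**2 + 1.0)


def weber_predictor_log(r_num):
    """Log-model probit predictor |log2 r_num|."""
    return np.abs(np.log2(np.asarray(r_num, dtype=float)))


def weber_predictor(model: str, covariates: pd.DataFrame):
    """Model-specific probit predictor(s) from a covariate table.

    ``linear`` and ``log`` return a 1-D array; ``modlog`` returns the
    (n, 3) signed design matrix [log2 r_num, log2 r_size, log2 r_spacing].
    """
    if model == "linear":
        return weber_predictor_linear(covariates["ratio_R"].to_numpy())
    if model == "log":
        return weber_predictor_log(covariates["r_num"].to_numpy())
    if model == "modlog":
        return np.column_stack(
            [
                np.log2(covariates["r_num"].to_numpy(dtype=float)),
                covariates["log2_r_size"].to_numpy(dtype=float),
                covariates["log2_r_spacing"].to_numpy(dtype=float),
            ]
        )
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# GLM fitting


@dataclass
class GlmFit:
    """A fitted binomial GLM with Wald statistics.

    ``coefficients`` etc. are indexed like ``names``; the intercept, when
    present, is first.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n: int
    link: str
    has_intercept: bool
    converged: bool
    names: tuple[str, ...] = field(default_factory=tuple)


def fit_probit_glm(
    y,
    X,
    has_intercept: bool = True,
    link: str = "probit",
    freq_weights=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit a binomial GLM by iteratively reweighted least squares.

    Parameters
    ----------
    y
        Binary outcome vector in {0, 1}.
    X
        Predictor matrix (n, p) or vector, *without* a constant column; a
        constant is prepended when ``has_intercept``.
    link
        ``"probit"`` or ``"logit"``.
    freq_weights
        Optional per-row frequency weights (aggregated Bernoulli data).

    Notes
    -----
    Degenerate data (all-constant outcome, complete separation, or a
    non-converged IRLS run) is reported with ``converged=False`` rather than
    a silently finite slope.  Separation is detected by the fitted linear
    predictor exceeding +-30, far outside any realistic probit scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary in {0, 1}")
    names: list[str] = [f"x{i}" for i in range(X.shape[1])]
    if has_intercept:
        X = sm.add_constant(X, prepend=True, has_constant="add")
        names = ["const", *names]
    n_obs = int(freq_weights.sum()) if freq_weights is not None else len(y)
    if n_obs <= X.shape[1]:
        raise ValueError("need more observations than coefficients")

    links = {"probit": sm.families.links.Probit(), "logit": sm.families.links.Logit()}
    family = sm.families.Binomial(link=links[link])

    weights = None if freq_weights is None else np.asarray(freq_weights, dtype=float)
    degenerate = y.min() == y.max()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=family, freq_weights=weights)
        try:
            res = model.fit(maxiter=max_iter, tol=tol)
        except Exception:
            return GlmFit(
                coefficients=np.full(X.shape[1], np.nan),
                standard_errors=np.full(X.shape[1], np.nan),
                p_values=np.full(X.shape[1], np.nan),
                log_likelihood=np.nan,
                n=n_obs,
                link=link,
                has_intercept=has_intercept,
                converged=False,
                names=tuple(names),
            )
    linpred = X @ res.params
    if (
        degenerate
        or not res.converged
        or not np.all(np.isfinite(res.params))
        or np.max(np.abs(linpred)) > MAX_ABS_LINPRED
    ):
        converged = False
    return GlmFit(
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(res.llf),
        n=n_obs,
        link=link,
        has_intercept=has_intercept,
        converged=converged,
        names=tuple(names),
    )


# ---------------------------------------------------------------------------
# Weber-fraction estimation


@dataclass
class WeberFit:
    """A per-participant Weber-fraction estimate.

    ``beta`` is the slope on the model's predictor (for modlog, the slope on
    log2 r_num); ``w`` follows the model-specific transform
    (linear: 1/beta, log and modlog: 1/(sqrt(2) beta)).  ``excluded`` applies
    the slope-significance rule; ``large_w`` additionally flags w > 2.
    """

    model: str
    beta: float
    beta_se: float
    beta_p: float
    w: float
    intercept: float | None
    beta_size: float | None
    beta_spacing: float | None
    converged: bool
    excluded: bool
    large_w: bool
    log_likelihood: float = np.nan
    n: int = 0


def _beta_to_w(model: str, beta: float) -> float:
    if beta <= 0 or not np.isfinite(beta):
        return np.nan
    if model == "linear":
        return 1.0 / beta
    return 1.0 / (SQRT2 * beta)


def fit_weber(trials: pd.DataFrame, model: str = "linear") -> WeberFit:
    """Estimate a participant's Weber fraction under one of the three models.

    The linear and log models fit a no-intercept probit of *correctness* on
    the model predictor; the modlog model fits an intercepted probit of the
    *chosen side* (right = 1) on signed log2 r_num plus the visual
    log-ratios, which must be present in the table.

    Returns a :class:`WeberFit`; degenerate fits carry ``converged=False``,
    ``excluded=True`` and ``w = nan``.
    """
    if model not in ("linear", "log", "modlog"):
        raise ValueError(f"unknown model {model!r}")
    needed = {"ratio_R", "r_num"} - set(trials.columns)
    if needed:
        from .trialdata import derive_covariates

        trials = derive_covariates(trials)
    X = weber_predictor(model, trials)
    if model == "modlog":
        y = (trials["response_side"] == "right").to_numpy(dtype=float)
        fit = fit_probit_glm(y, X, has_intercept=True)
        intercept = float(fit.coefficients[0])
        beta, se, p = (float(fit.coefficients[1]), float(fit.standard_errors[1]),
                       float(fit.p_values[1]))
        beta_size = float(fit.coefficients[2])
        beta_spacing = float(fit.coefficients[3])
    else:
        if np.unique(np.round(X, 12)).size < 2:
            raise ValueError("need at least two distinct predictor values")
        y = trials["correct"].to_numpy(dtype=float)
        fit = fit_probit_glm(y, X, has_intercept=False)
        intercept = None
        beta, se, p = (float(fit.coefficients[0]), float(fit.standard_errors[0]),
                       float(fit.p_values[0]))
        beta_size = beta_spacing = None

    w = _beta_to_w(model, beta) if fit.converged else np.nan
    excluded = (not fit.converged) or (not np.isfinite(p)) or p >= ALPHA_EXCLUSION or beta <= 0
    return WeberFit(
        model=model,
        beta=beta,
        beta_se=se,
        beta_p=p,
        w=w,
        intercept=intercept,
        beta_size=beta_size,
        beta_spacing=beta_spacing,
        converged=fit.converged,
        excluded=bool(excluded),
        large_w=bool(np.isfinite(w) and w > LARGE_W),
        log_likelihood=fit.log_likelihood,
        n=fit.n,
    )


def lr_test_predictor(full: GlmFit, reduced: GlmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test for dropped predictor(s).

    ``chi2 = 2 (llf_full - llf_reduced)`` on df equal to the difference in
    coefficient counts.  The reduced model must be nested in the full one
    (same data size, fewer coefficients, same link).
    """
    if reduced.n != full.n or reduced.link != full.link:
        raise ValueError("models were not fitted to the same data")
    df = len(full.coefficients) - len(reduced.coefficients)
    if df <= 0:
        if df == 0 and np.isclose(full.log_likelihood, reduced.log_likelihood):
            return 0.0, 0, 1.0
        raise ValueError("reduced model is not nested in the full model")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p
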