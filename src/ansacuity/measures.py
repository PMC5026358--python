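"""Per-participant ANS acuity indices.

Eleven indices per participant x condition, as commonly reported for
two-alternative dot comparison:

accuracy based
    mean accuracy; NDE_acc and NRE_acc (probit-GLM slopes of correctness on
    numerical distance D = |n1 - n2| and ratio R = min/max); Weber fractions
    under the linear, log and modified-log models.
response-time based
    mean RT (over all responses by default); NDE_RT and NRE_RT (OLS slopes
    of RT on D and R), in ms per unit predictor.
composite
    inverse efficiency score (mean correct-response RT / proportion correct,
    in ms); z-composite (average of the across-participant z-scores of mean
    accuracy and mean RT).

Slopes are per unit predictor internally; ``slope_scale="per0.1"`` rescales
ratio slopes to a 0.1 ratio increment for reporting.  A linear-model ratio
effect on percent correct (used as a manipulation check across conditions)
is provided separately from the probit NRE_acc.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .psychomodels import fit_probit_glm, fit_weber
from .trialdata import derive_covariates

__all__ = [
    "mean_accuracy",
    "mean_rt",
    "inverse_efficiency",
    "effect_slope_acc",
    "effect_slope_rt",
    "ratio_effect_linear_percent",
    "z_composite",
    "compute_all_measures",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = (
    "mean_acc",
    "nde_acc",
    "nre_acc",
    "w_lin",
    "w_log",
    "w_modlog",
    "mean_rt",
    "nde_rt",
    "nre_rt",
    "ies",
    "z_comp",
)

_PREDICTOR_COL = {"distance": "distance_D", "ratio": "ratio_R"}


def _with_covariates(trials: pd.DataFrame) -> pd.DataFrame:
    if {"ratio_R", "distance_D", "r_num"} - set(trials.columns):
        return derive_covariates(trials)
    return trials


def mean_accuracy(trials: pd.DataFrame) -> float:
    """Fraction of correct trials, pooling all ratios."""
    if len(trials) == 0:
        raise ValueError("cannot compute accuracy of an empty trial set")
    return float(trials["correct"].mean())


def mean_rt(trials: pd.DataFrame, which: str = "all") -> float:
    """Arithmetic mean RT in ms over all, or correct-only, responses."""
    if which not in ("all", "correct_only"):
        raise ValueError(f"unknown subset {which!r}")
    subset = trials if which == "all" else trials[trials["correct"]]
    if len(subset) == 0:
        raise ValueError(f"empty {which!r} subset")
    return float(subset["rt_ms"].mean())


def inverse_efficiency(trials: pd.DataFrame) -> float:
    """Mean correct-response RT divided by proportion correct, in ms."""
    acc = mean_accuracy(trials)
    if acc == 0:
        raise ValueError("inverse efficiency undefined at zero accuracy")
    return mean_rt(trials, "correct_only") / acc


def effect_slope_acc(
    trials: pd.DataFrame, predictor: str = "ratio", slope_scale: str = "unit"
) -> float:
    """Probit-GLM slope of correctness on distance (NDE_acc) or ratio (NRE_acc).

    The model includes an intercept.  Returns NaN for degenerate fits.
    ``slope_scale="per0.1"`` rescales a ratio slope to per-0.1 increments.
    """
    trials = _with_covariates(trials)
    x = trials[_PREDICTOR_COL[predictor]].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two predictor values")
    fit = fit_probit_glm(trials["correct"].to_numpy(dtype=float), x, has_intercept=True)
    if not fit.converged:
        return np.nan
    slope = float(fit.coefficients[1])
    if predictor == "ratio" and slope_scale == "per0.1":
        slope *= 0.1
    return slope


def effect_slope_rt(
    trials: pd.DataFrame, predictor: str = "ratio", slope_scale: str = "unit"
) -> float:
    """OLS slope of RT (ms) on distance (NDE_RT) or ratio (NRE_RT)."""
    trials = _with_covariates(trials)
    x = trials[_PREDICTOR_COL[predictor]].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("predictor has zero variance")
    y = trials["rt_ms"].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    if predictor == "ratio" and slope_scale == "per0.1":
        slope *= 0.1
    return slope


def ratio_effect_linear_percent(
    trials: pd.DataFrame, slope_scale: str = "per0.1"
) -> float:
    """Linear-model ratio effect on percent correct.

    OLS slope of per-ratio mean accuracy (in %) on the ratio, the
    manipulation-check variant of NRE_acc (distinct from the probit slope).
    Default scaling is percent per 0.1 ratio increment.
    """
    trials = _with_covariates(trials)
    by_ratio = trials.groupby("ratio_bin", observed=True)["correct"].mean() * 100.0
    if len(by_ratio) < 2:
        raise ValueError("need at least two ratio bins")
    x = by_ratio.index.to_numpy(dtype=float)
    res = sm.OLS(by_ratio.to_numpy(), sm.add_constant(x)).fit()
    slope = float(res.params[1])
    return slope * 0.1 if slope_scale == "per0.1" else slope


def z_composite(cohort: pd.DataFrame) -> pd.Series:
    """Average of across-cohort z-scores of mean accuracy and mean RT.

    ``cohort`` must have columns ``mean_acc`` and ``mean_rt`` (one row per
    participant, within a single condition).  No sign flip is applied, so the
    composite correlates positively with both inputs.
    """
    if len(cohort) < 2:
        raise ValueError("z-composite needs a cohort of at least 2")
    out = np.zeros(len(cohort))
    for col in ("mean_acc", "mean_rt"):
        x = cohort[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in {col!r}")
        out += (x - x.mean()) / sd
    return pd.Series(out / 2.0, index=cohort.index, name="z_comp")


def compute_all_measures(
    trials: pd.DataFrame,
    slope_scale: str = "unit",
    group_cols: tuple[str, ...] = ("participant_id", "condition"),
) -> pd.DataFrame:
    """Compute the full measure table, one row per participant x condition.

    Expects trimmed trials.  Weber fits failing the slope-significance
    exclusion rule keep their flags but have ``w_* = NaN``; the modlog model
    is fitted only when visual log-ratios are present.  The z-composite is
    computed within condition across the cohort.
    """
    trials = _with_covariates(trials)
    has_visual = (
        "log2_r_size" in trials.columns
        and "log2_r_spacing" in trials.columns
        and trials["log2_r_size"].notna().all()
    )
    rows = []
    for name, grp in trials.groupby(list(group_cols), sort=True, observed=True):
        rec: dict = dict(zip(group_cols, name if isinstance(name, tuple) else (name,)))
        rec["n_trials"] = len(grp)
        rec["mean_acc"] = mean_accuracy(grp)
        rec["nde_acc"] = effect_slope_acc(grp, "distance")
        rec["nre_acc"] = effect_slope_acc(grp, "ratio", slope_scale=slope_scale)
        for model, col in (("linear", "w_lin"), ("log", "w_log")):
            fit = fit_weber(grp, model)
            rec[col] = fit.w if not fit.excluded else np.nan
            rec[f"{col}_excluded"] = fit.excluded
        if has_visual:
            fit = fit_weber(grp, "modlog")
            rec["w_modlog"] = fit.w if not fit.excluded else np.nan
            rec["w_modlog_excluded"] = fit.excluded
        else:
            rec["w_modlog"] = np.nan
            rec["w_modlog_excluded"] = True
        has_rt = grp["rt_ms"].notna().all() if "rt_ms" in grp.columns else False
        if has_rt:
            rec["mean_rt"] = mean_rt(grp, "all")
            rec["nde_rt"] = effect_slope_rt(grp, "distance")
            rec["nre_rt"] = effect_slope_rt(grp, "ratio", slope_scale=slope_scale)
            rec["ies"] = inverse_efficiency(grp)
        else:
            rec["mean_rt"] = rec["nde_rt"] = rec["nre_rt"] = rec["ies"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["z_comp"] = np.nan
    if out["mean_rt"].notna().all():
        for _, idx in out.groupby("condition", observed=True).groups.items():
            sub = out.loc[idx]
            if len(sub) >= 2 and sub["mean_acc"].std(ddof=1) > 0 and sub["mean_rt"].std(ddof=1) > 0:
                out.loc[idx, "z_comp"] = z_composite(sub)
    return out
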