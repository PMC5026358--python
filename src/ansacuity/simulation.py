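"""Binomial simulation of the ratio-effect / Weber-fraction relationship.

For a grid of true Weber fractions, per-ratio correct counts are drawn from
``Binomial(items_per_ratio, p)`` with p given by the linear-model accuracy
prediction, and the accuracy ratio effect (NRE_acc) of each simulated
participant is estimated three ways:

1. OLS slope of proportion correct on the ratio (linear, continuous);
2. categorical contrast
   ``(mean acc at large ratios - mean acc at small ratios) / mean acc at
   large ratios`` (default split: small {0.5, 0.6}, large {0.8, 0.9});
3. probit-GLM slope of trial-level correctness on the ratio.

The per-w means of the three estimators reveal the key methodological
property: both linear-model estimators are curvilinear functions of the
Weber fraction (an interior extremum, so a given NRE value is ambiguous
between sharp and poor acuity), while the probit estimator is monotone in w.
``shape_diagnostics`` tests these shapes on a smoothed curve with a
noise tolerance tied to the per-w standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .psychomodels import fit_probit_glm, predict_accuracy_linear

__all__ = [
    "SimGrid",
    "simulate_binomial_participant",
    "nre_three_ways",
    "run_grid",
    "shape_diagnostics",
    "plot_grid_summary",
]

SMOOTH_WINDOW = 5  # moving-average window for shape diagnostics
SE_TOLERANCE_FACTOR = 2.0  # noise tolerance = factor x median per-w SE

DEFAULT_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9)
SMALL_RATIOS = (0.5, 0.6)
LARGE_RATIOS = (0.8, 0.9)


@dataclass
class SimGrid:
    """Simulation design: Weber-fraction grid x simulated cohort."""

    w_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.10, 0.901, 0.01), 2)
    )
    participants_per_w: int = 100
    items_per_ratio: int = 80
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    seed: int = 0

    def __post_init__(self):
        self.w_values = np.asarray(self.w_values, dtype=float)
        if not np.all(np.diff(self.w_values) > 0):
            raise ValueError("w_values must be strictly increasing")
        if np.any(self.w_values <= 0):
            raise ValueError("Weber fractions must be positive")


def simulate_binomial_participant(
    w: float, ratios=DEFAULT_RATIOS, items_per_ratio: int = 80,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Per-ratio correct counts for one simulated participant.

    Counts are Binomial(items_per_ratio, p) with p the linear-model accuracy
    at each design ratio for Weber fraction ``w``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = predict_accuracy_linear(np.asarray(ratios, dtype=float), w)
    return rng.binomial(items_per_ratio, p)


def nre_three_ways(
    counts,
    ratios=DEFAULT_RATIOS,
    items_per_ratio: int = 80,
    small=SMALL_RATIOS,
    large=LARGE_RATIOS,
) -> dict:
    """Three ratio-effect estimators from per-ratio correct counts.

    Returns a dict with keys ``linear_continuous`` (OLS slope of proportion
    correct per unit ratio), ``categorical`` (relative large-vs-small
    accuracy contrast), and ``probit`` (probit-GLM slope on the ratio; NaN
    when the fit is degenerate).
    """
    ratios = np.asarray(ratios, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != ratios.shape:
        raise ValueError("one count per design ratio is required")
    props = counts / items_per_ratio

    ols = sm.OLS(props, sm.add_constant(ratios)).fit()
    linear_continuous = float(ols.params[1])

    small_mask = np.isin(ratios, small)
    large_mask = np.isin(ratios, large)
    acc_small = props[small_mask].mean()
    acc_large = props[large_mask].mean()
    categorical = (acc_large - acc_small) / acc_large if acc_large > 0 else np.nan

    # trial-level probit via frequency-weighted Bernoulli rows
    y = np.concatenate([np.ones_like(ratios), np.zeros_like(ratios)])
    x = np.concatenate([ratios, ratios])
    weights = np.concatenate([counts, items_per_ratio - counts])
    keep = weights > 0
    fit = fit_probit_glm(
        y[keep], x[keep], has_intercept=True, freq_weights=weights[keep]
    )
    probit = float(fit.coefficients[1]) if fit.converged else np.nan
    return {
        "linear_continuous": linear_continuous,
        "categorical": float(categorical),
        "probit": probit,
    }


def run_grid(grid: SimGrid) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full sweep over the Weber-fraction grid.

    Returns ``(per_participant, summary)``: one row per (w, participant)
    with the three estimators, and per-w means / standard errors over
    converged fits.  Deterministic given ``grid.seed``.
    """
    rng = np.random.default_rng(grid.seed)
    rows = []
    for w in grid.w_values:
        for p_idx in range(grid.participants_per_w):
            counts = simulate_binomial_participant(
                w, grid.ratios, grid.items_per_ratio, rng
            )
            est = nre_three_ways(counts, grid.ratios, grid.items_per_ratio)
            rows.append({"w": w, "participant": p_idx, **est})
    per_participant = pd.DataFrame(rows)

    agg = per_participant.groupby("w", sort=True)
    summary = agg.agg(
        nre_linear_mean=("linear_continuous", "mean"),
        nre_linear_se=("linear_continuous", "sem"),
        nre_categorical_mean=("categorical", "mean"),
        nre_categorical_se=("categorical", "sem"),
        nre_probit_mean=("probit", "mean"),
        nre_probit_se=("probit", "sem"),
        n_converged_probit=("probit", "count"),
    ).reset_index()
    return per_participant, summary


def _smooth(x: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _curve_shape(mean: np.ndarray, se: np.ndarray) -> dict:
    c = _smooth(mean)
    tol = SE_TOLERANCE_FACTOR * float(np.nanmedian(se))
    # monotone: no excursion against either direction larger than the tolerance
    max_decrease = float(np.max(np.maximum.accumulate(c) - c))
    max_increase = float(np.max(c - np.minimum.accumulate(c)))
    monotone = max_decrease <= tol or max_increase <= tol
    # interior extremum: the smoothed extremum sits strictly inside the grid
    # and both endpoints clear it by more than the tolerance
    interior_extremum = False
    for ext in (int(np.argmin(c)), int(np.argmax(c))):
        if 0 < ext < len(c) - 1:
            drop0 = abs(c[0] - c[ext])
            drop1 = abs(c[-1] - c[ext])
            same_side = (c[0] - c[ext]) * (c[-1] - c[ext]) > 0
            if same_side and drop0 > tol and drop1 > tol:
                interior_extremum = True
    return {
        "monotone": bool(monotone),
        "interior_extremum": interior_extremum,
        "tolerance": tol,
    }


def shape_diagnostics(summary: pd.DataFrame) -> dict:
    """Shape report for the three per-w mean estimator curves.

    Each curve is smoothed with a centered 5-point moving average;
    excursions smaller than twice the median per-w standard error count as
    noise.  A curve is *monotone* when it never moves against one direction
    by more than the tolerance, and has an *interior extremum* when the
    smoothed extremum sits strictly inside the grid with both endpoints
    clearing it by more than the tolerance.
    """
    if len(summary) < 5:
        raise ValueError("need at least 5 grid points for shape diagnostics")
    out = {}
    for key, mean_col, se_col in (
        ("linear", "nre_linear_mean", "nre_linear_se"),
        ("categorical", "nre_categorical_mean", "nre_categorical_se"),
        ("probit", "nre_probit_mean", "nre_probit_se"),
    ):
        out[key] = _curve_shape(
            summary[mean_col].to_numpy(dtype=float),
            summary[se_col].to_numpy(dtype=float),
        )
    return out


def plot_grid_summary(summary: pd.DataFrame, path) -> None:
    """Three-panel plot of the per-w mean NRE under each estimator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    panels = (
        ("nre_linear_mean", "nre_linear_se", "linear (continuous)"),
        ("nre_categorical_mean", "nre_categorical_se", "linear (categorical)"),
        ("nre_probit_mean", "nre_probit_se", "probit GLM"),
    )
    for ax, (mean_col, se_col, title) in zip(axes, panels):
        w = summary["w"]
        m = summary[mean_col]
        ax.plot(w, m, "-", lw=1.5)
        ax.fill_between(w, m - summary[se_col], m + summary[se_col], alpha=0.3)
        ax.set_title(title)
        ax.set_xlabel("Weber fraction w")
    axes[0].set_ylabel("mean NRE_acc")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
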