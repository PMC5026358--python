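"""Spearman correlation matrices with Benjamini-Hochberg adjustment.

Measure tables are correlated pairwise-complete (participants missing a
measure -- e.g. through the Weber-fraction exclusion rule -- are dropped per
pair, not listwise).  The multiple-testing family is the set of unique
measure pairs within one condition table, adjusted by the Benjamini-Hochberg
step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationMatrix", "spearman_rho", "bh_adjust", "correlation_table"]


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value.

    Ranks are averaged over ties.  Pairs with a missing member are dropped.
    Returns ``(nan, nan)`` when either input has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p(i) are multiplied by m/i, monotonicity is enforced from the
    largest down, values are capped at 1, and the original order restored.
    NaNs pass through unchanged and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman matrix with raw and adjusted p-values."""

    labels: tuple[str, ...]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_pairs: np.ndarray

    def to_long(self) -> pd.DataFrame:
        """Lower-triangle long format (measure_a, measure_b, rho, p_raw, p_adj, n)."""
        rows = []
        k = len(self.labels)
        for i in range(1, k):
            for j in range(i):
                rows.append(
                    {
                        "measure_a": self.labels[i],
                        "measure_b": self.labels[j],
                        "rho": self.rho[i, j],
                        "p_raw": self.p_raw[i, j],
                        "p_adj": self.p_adj[i, j],
                        "n": int(self.n_pairs[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def correlation_table(
    measures: pd.DataFrame, columns: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise-complete Spearman matrix over measure columns.

    BH adjustment is applied across the lower triangle (one family per
    table/condition, mirroring per-table significance marks).
    """
    if columns is None:
        columns = [
            c
            for c in measures.columns
            if measures[c].dtype.kind in "fi" and not c.endswith("_excluded")
            and c not in ("n_trials",)
        ]
    k = len(columns)
    rho = np.eye(k)
    p_raw = np.zeros((k, k))
    n_pairs = np.zeros((k, k), dtype=int)
    for i in range(k):
        n_pairs[i, i] = measures[columns[i]].notna().sum()
        for j in range(i):
            x = measures[columns[i]].to_numpy(dtype=float)
            y = measures[columns[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n_pairs[i, j] = n_pairs[j, i] = int(ok.sum())
            if ok.sum() < 3:
                rho[i, j] = rho[j, i] = np.nan
                p_raw[i, j] = p_raw[j, i] = np.nan
                continue
            r, p = spearman_rho(x[ok], y[ok])
            rho[i, j] = rho[j, i] = r
            p_raw[i, j] = p_raw[j, i] = p

    tril = np.tril_indices(k, k=-1)
    p_adj = np.zeros((k, k))
    adj = bh_adjust(p_raw[tril])
    p_adj[tril] = adj
    p_adj = p_adj + p_adj.T
    return CorrelationMatrix(
        labels=tuple(columns), rho=rho, p_raw=p_raw, p_adj=p_adj, n_pairs=n_pairs
    )
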