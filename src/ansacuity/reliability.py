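"""Split-half reliability with repeated random splits.

For each replicate, every participant's trials are randomly partitioned into
two equal halves; the measure of interest is computed on each half; the two
half-vectors are correlated across participants (Pearson), and the half-test
correlation is stepped up to full test length with the Spearman-Brown
prophecy formula ``2 r / (1 + r)``.  Both the uncorrected and corrected
values are averaged over replicates (the correction is applied per replicate
before averaging; ``correct_after_average=True`` selects the alternative of
averaging first).

The split is simple random by default; ``stratify_by_ratio=True`` instead
splits within each ratio bin, keeping the two halves balanced by design
ratio.  Odd trial counts assign the extra trial to a half by a seeded draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["ReliabilityResult", "spearman_brown", "split_half"]


@dataclass
class ReliabilityResult:
    measure_name: str
    mean_uncorrected: float
    mean_corrected: float
    n_replicates: int
    seed: int
    mean_fraction_dropped: float = 0.0

    @property
    def corrected_clipped(self) -> float:
        """Corrected value clipped to <= 1 for reporting."""
        return min(self.mean_corrected, 1.0)


def spearman_brown(r_half: float) -> float:
    """Step a half-test correlation up to full test length: 2r / (1 + r)."""
    if r_half <= -1.0:
        raise ValueError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r_half / (1.0 + r_half)


def _split_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask for half A; sizes differ by at most one (seeded draw)."""
    mask = np.zeros(n, dtype=bool)
    half = n // 2
    if n % 2 and rng.random() < 0.5:
        half += 1
    mask[rng.permutation(n)[:half]] = True
    return mask


def split_half(
    trials: pd.DataFrame,
    measure_fn: Callable[[pd.DataFrame], float],
    n_replicates: int = 100,
    seed: int = 0,
    measure_name: str = "measure",
    stratify_by_ratio: bool = False,
    correct_after_average: bool = False,
) -> ReliabilityResult:
    """Repeated random-split reliability of a per-participant measure.

    ``measure_fn`` maps one participant's half-set of trials to a scalar;
    a NaN return (or raised ValueError) marks the measure undefined on that
    half, and such participants are dropped pairwise from that replicate's
    correlation.  Fixed ``seed`` gives a bit-identical result.
    """
    rng = np.random.default_rng(seed)
    groups = [grp for _, grp in trials.groupby("participant_id", sort=True, observed=True)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every participant needs at least 2 trials")

    raw, corrected, dropped = [], [], []
    for _ in range(n_replicates):
        a_vals, b_vals = [], []
        for grp in groups:
            if stratify_by_ratio and "ratio_bin" in grp.columns:
                mask = np.zeros(len(grp), dtype=bool)
                pos = 0
                for _, sub in grp.groupby("ratio_bin", observed=True):
                    m = _split_indices(len(sub), rng)
                    mask[grp.index.get_indexer(sub.index)] = m
                    pos += len(sub)
            else:
                mask = _split_indices(len(grp), rng)
            vals = []
            for half in (grp.loc[mask], grp.loc[~mask]):
                try:
                    vals.append(float(measure_fn(half)))
                except ValueError:
                    vals.append(np.nan)
            a_vals.append(vals[0])
            b_vals.append(vals[1])
        a = np.asarray(a_vals)
        b = np.asarray(b_vals)
        ok = np.isfinite(a) & np.isfinite(b)
        dropped.append(1.0 - ok.mean())
        if ok.sum() < 3:
            raw.append(np.nan)
            corrected.append(np.nan)
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        raw.append(r)
        corrected.append(spearman_brown(r) if r > -1.0 else np.nan)

    mean_raw = float(np.nanmean(raw))
    if correct_after_average:
        mean_corr = spearman_brown(mean_raw)
    else:
        mean_corr = float(np.nanmean(corrected))
    return ReliabilityResult(
        measure_name=measure_name,
        mean_uncorrected=mean_raw,
        mean_corrected=mean_corr,
        n_replicates=n_replicates,
        seed=seed,
        mean_fraction_dropped=float(np.mean(dropped)),
    )
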