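"""Trial-level data handling for two-alternative dot-comparison experiments.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with one
row per trial.  Mandatory columns:

``participant_id, experiment, condition, n_left, n_right, response_side,
correct, rt_ms``

with optional visual-feature columns ``log2_r_size`` and ``log2_r_spacing``
(DeWind-style right/left log-ratios of dot size and spacing) and an optional
``rt_time_base`` tag (``"offset"`` or ``"onset"``) recording, per condition,
whether response time is measured from stimulus offset (restricted
presentation durations) or stimulus onset (self-paced presentation).  Unknown
columns are preserved untouched by every operation in this module.

Derived per-trial covariates:

* ``ratio_R``  -- min(n1, n2) / max(n1, n2), in (0, 1)
* ``distance_D`` -- \\|n1 - n2\\|
* ``r_num``   -- n_right / n_left
* ``ratio_bin`` -- the design ratio the trial belongs to
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "validate_trials",
    "derive_covariates",
    "enumerate_ratio_pairs",
    "build_item_set",
    "trim_rts",
    "read_trials",
    "write_trials",
    "read_trials_xlsx",
]

REQUIRED_COLUMNS = (
    "participant_id",
    "experiment",
    "condition",
    "n_left",
    "n_right",
    "response_side",
    "correct",
    "rt_ms",
)
OPTIONAL_COLUMNS = ("log2_r_size", "log2_r_spacing", "rt_time_base")

_SIDES = frozenset({"left", "right"})


def validate_trials(trials: pd.DataFrame, require_rt: bool = True) -> pd.DataFrame:
    """Validate a trial table against the container invariants.

    Checks column presence, numerosity positivity, the no-tie rule
    (``n_left != n_right``), response-side labels, agreement of ``correct``
    with the side of the larger set, and non-negative response times.

    Parameters
    ----------
    trials
        Tidy trial table.
    require_rt
        When ``False``, ``rt_ms`` may be absent or NaN (accuracy-only data).

    Returns
    -------
    pandas.DataFrame
        The input, with ``n_left``/``n_right`` coerced to integers and
        ``correct`` to boolean.

    Raises
    ------
    ValueError
        Naming the missing column, or the 0-based row index of the first
        malformed row.
    """
    required = REQUIRED_COLUMNS if require_rt else tuple(
        c for c in REQUIRED_COLUMNS if c != "rt_ms"
    )
    for col in required:
        if col not in trials.columns:
            raise ValueError(f"trial table is missing mandatory column {col!r}")

    df = trials.copy()
    for col in ("n_left", "n_right"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != values.round()) | (values < 1)
        if bad.any():
            raise ValueError(
                f"malformed {col!r} at row {int(np.flatnonzero(bad.to_numpy())[0])}"
            )
        df[col] = values.astype(int)

    ties = df["n_left"].to_numpy() == df["n_right"].to_numpy()
    if ties.any():
        raise ValueError(
            "equal numerosities (undefined comparison) at row "
            f"{int(np.flatnonzero(ties)[0])}"
        )

    side = df["response_side"].astype(str)
    bad_side = ~side.isin(_SIDES)
    if bad_side.any():
        raise ValueError(
            f"malformed 'response_side' at row {int(np.flatnonzero(bad_side.to_numpy())[0])}"
        )
    df["response_side"] = side

    correct = df["correct"]
    if correct.dtype != bool:
        mapped = correct.map(
            {True: True, False: False, 1: True, 0: False, "True": True,
             "False": False, "true": True, "false": False}
        )
        if mapped.isna().any():
            raise ValueError(
                f"malformed 'correct' at row {int(np.flatnonzero(mapped.isna().to_numpy())[0])}"
            )
        df["correct"] = mapped.astype(bool)

    larger_right = df["n_right"].to_numpy() > df["n_left"].to_numpy()
    chose_right = (df["response_side"] == "right").to_numpy()
    implied = chose_right == larger_right
    mismatch = implied != df["correct"].to_numpy()
    if mismatch.any():
        raise ValueError(
            "'correct' inconsistent with response side and numerosities at row "
            f"{int(np.flatnonzero(mismatch)[0])}"
        )

    if "rt_ms" in df.columns:
        rt = pd.to_numeric(df["rt_ms"], errors="coerce")
        if require_rt:
            bad_rt = rt.isna() | (rt < 0)
        else:
            bad_rt = rt.notna() & (rt < 0)
        if bad_rt.any():
            raise ValueError(
                f"malformed 'rt_ms' at row {int(np.flatnonzero(bad_rt.to_numpy())[0])}"
            )
        df["rt_ms"] = rt
    return df


def derive_covariates(
    trials: pd.DataFrame, design_ratios: Sequence[float] | None = None
) -> pd.DataFrame:
    """Append the numerical covariates ratio_R, distance_D, r_num, ratio_bin.

    ``ratio_R = min(n1, n2) / max(n1, n2)``, ``distance_D = |n1 - n2|`` and
    ``r_num = n_right / n_left``.  ``ratio_bin`` snaps ``ratio_R`` to the
    nearest design ratio when ``design_ratios`` is given, else equals
    ``ratio_R`` (exact by construction for generated item sets).

    Raises
    ------
    ValueError
        If any trial has equal numerosities.
    """
    df = validate_trials(trials, require_rt=False)
    n_left = df["n_left"].to_numpy(dtype=float)
    n_right = df["n_right"].to_numpy(dtype=float)
    df["ratio_R"] = np.minimum(n_left, n_right) / np.maximum(n_left, n_right)
    df["distance_D"] = np.abs(n_left - n_right).astype(int)
    df["r_num"] = n_right / n_left
    if design_ratios is not None:
        bins = np.asarray(sorted(design_ratios), dtype=float)
        idx = np.argmin(np.abs(df["ratio_R"].to_numpy()[:, None] - bins[None, :]), axis=1)
        df["ratio_bin"] = bins[idx]
    else:
        df["ratio_bin"] = df["ratio_R"]
    return df


def enumerate_ratio_pairs(ratio: float, n_min: int, n_max: int) -> list[tuple[int, int]]:
    """Enumerate all (smaller, larger) integer pairs with exact min/max ratio.

    The nominal ratio is interpreted as a rational number (e.g. 0.7 -> 7/10);
    pairs are multiples ``(k*p, k*q)`` of the reduced fraction ``p/q`` with
    both members inside ``[n_min, n_max]``.
    """
    frac = Fraction(ratio).limit_denominator(1000)
    p, q = frac.numerator, frac.denominator
    if not 0 < p < q:
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    pairs = []
    k = 1
    while k * q <= n_max:
        if k * p >= n_min:
            pairs.append((k * p, k * q))
        k += 1
    return pairs


def build_item_set(
    ratios: Iterable[float],
    n_min: int = 10,
    n_max: int = 40,
    trials_per_ratio: int = 80,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Construct a balanced comparison item set.

    For each design ratio, draws ``trials_per_ratio`` items uniformly (with
    replacement) from the integer pairs whose exact min/max ratio equals the
    nominal ratio.  The side of the larger set is counterbalanced: half the
    items place the larger set on the left, half on the right, with an odd
    remainder assigned by a seeded draw.  Item order is shuffled.

    Returns
    -------
    pandas.DataFrame
        Columns ``n_left, n_right, ratio_bin``.

    Raises
    ------
    ValueError
        Naming any ratio with no exact integer pair in range.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        pairs = enumerate_ratio_pairs(ratio, n_min, n_max)
        if not pairs:
            raise ValueError(
                f"no exact integer pair with ratio {ratio} in [{n_min}, {n_max}]"
            )
        idx = rng.integers(0, len(pairs), size=trials_per_ratio)
        half = trials_per_ratio // 2
        larger_left = np.zeros(trials_per_ratio, dtype=bool)
        larger_left[:half] = True
        if trials_per_ratio % 2:
            larger_left[-1] = rng.random() < 0.5
        rng.shuffle(larger_left)
        for i, flip in zip(idx, larger_left):
            small, large = pairs[i]
            if flip:
                rows.append((large, small, ratio))
            else:
                rows.append((small, large, ratio))
    items = pd.DataFrame(rows, columns=["n_left", "n_right", "ratio_bin"])
    return items.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31))).reset_index(drop=True)


def trim_rts(
    trials: pd.DataFrame,
    k: float = 3.0,
    group_cols: Sequence[str] = ("participant_id", "condition"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove response-time outliers beyond ``k`` SD of each group's mean.

    Trimming is a single pass per participant x condition group (mean and SD
    computed once on the full group, both tails).  Groups with zero SD, or
    with fewer than two trials, are left untouched.

    Returns
    -------
    kept, report
        ``kept`` is the trial table without the outliers; ``report`` has one
        row per group (``n_total, n_removed, fraction_removed``) plus a final
        ``"<overall>"`` row.
    """
    if not math.isfinite(k):
        report = pd.DataFrame(
            [{"group": "<overall>", "n_total": len(trials), "n_removed": 0,
              "fraction_removed": 0.0}]
        )
        return trials.copy(), report

    keep = np.ones(len(trials), dtype=bool)
    records = []
    grouped = trials.groupby(list(group_cols), sort=False, observed=True)
    for name, grp in grouped:
        rt = grp["rt_ms"].to_numpy(dtype=float)
        if len(rt) >= 2:
            sd = rt.std(ddof=1)
            if sd > 0:
                out = np.abs(rt - rt.mean()) > k * sd
                keep[trials.index.get_indexer(grp.index)] &= ~out
        n_removed = int(len(rt) - keep[trials.index.get_indexer(grp.index)].sum())
        records.append(
            {"group": name, "n_total": len(rt), "n_removed": n_removed,
             "fraction_removed": n_removed / len(rt) if len(rt) else 0.0}
        )
    n_total = len(trials)
    n_removed = int(n_total - keep.sum())
    records.append(
        {"group": "<overall>", "n_total": n_total, "n_removed": n_removed,
         "fraction_removed": n_removed / n_total if n_total else 0.0}
    )
    return trials.loc[keep].copy(), pd.DataFrame(records)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a validated trial table as comma-separated UTF-8 with header."""
    validate_trials(trials, require_rt=False)
    trials.to_csv(path, index=False)


def read_trials(path, require_rt: bool = True) -> pd.DataFrame:
    """Read and validate a canonical trial CSV.

    Round-trips losslessly with :func:`write_trials`; unknown columns are
    preserved as opaque extras.
    """
    df = pd.read_csv(path)
    return validate_trials(df, require_rt=require_rt)


def read_trials_xlsx(
    path, column_map: Mapping[str, str], sheet_name: int | str = 0,
    require_rt: bool = True,
) -> pd.DataFrame:
    """Convenience reader for spreadsheet trial exports.

    ``column_map`` maps canonical column names to the spreadsheet's column
    headers (the layouts of deposited supplementary files vary, so the
    mapping must be supplied).  Requires ``openpyxl``.
    """
    raw = pd.read_excel(path, sheet_name=sheet_name)
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"spreadsheet is missing mapped columns {missing}")
    df = raw.rename(columns={src: dst for dst, src in column_map.items()})
    return validate_trials(df, require_rt=require_rt)
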