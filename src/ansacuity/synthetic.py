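"""Synthetic dot-comparison experiments with known ground truth.

The generator produces full trial tables with the statistical structure the
analysis stack assumes:

* **choice and RT** come from a drift-diffusion responder: evidence starts
  midway between two absorbing bounds 0 and a (response threshold), drifts
  at rate ``v = sign(log2 r_num) * v_scale * |log2 r_num| / w`` (sharper
  representations, i.e. smaller Weber fraction w, give stronger evidence)
  with unit diffusion noise, simulated by Euler-Maruyama steps; the upper
  bound maps to "choose right".  RT = first-passage time + non-decision
  time t0.  Conditions (task instruction or presentation duration) scale
  the threshold and may shift t0, moving the speed-accuracy criterion
  without touching the underlying Weber fraction.  The drift-w link is a
  modeling choice of this generator, not an estimate from data.

* **visual features** are DeWind-style log-ratios: ``log2 r_size`` is the
  sum of item-surface-area and total-surface-area log-ratios and ``log2
  r_spacing`` the sum of field-area and sparsity log-ratios, with a
  congruency mix controlling how often the visual cues favor the more
  numerous side.

* **accuracy-only sampling** (no RT machinery) draws Bernoulli responses
  directly from one of the three accuracy models, for estimator tests and
  the binomial simulation study.

Because accuracy in a diffusion process depends on the product of drift and
threshold, criterion shifts do move accuracy (and hence accuracy-derived
Weber estimates) in this generator; RT and accuracy move together, which is
exactly the speed-accuracy trade-off regime the analyses probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .psychomodels import (
    predict_accuracy_linear,
    predict_choose_right_log,
    predict_choose_right_modlog,
)
from .trialdata import build_item_set, derive_covariates

__all__ = [
    "DDMParams",
    "ConditionSpec",
    "GeneratorConfig",
    "generate_visual_features",
    "ddm_sample",
    "generate_experiment",
    "generate_accuracy_only",
]


@dataclass
class DDMParams:
    """Diffusion parameters: threshold a (evidence units), drift scale
    v_scale (evidence/s per unit |log2 r_num| at w = 1), non-decision time
    t0 (s), noise s (evidence/sqrt(s), fixed 1), Euler step dt (s)."""

    a: float = 1.0
    v_scale: float = 1.0
    t0: float = 0.25
    s: float = 1.0
    dt: float = 0.001
    max_time: float = 10.0

    def __post_init__(self):
        if self.a <= 0 or self.dt <= 0 or self.s <= 0 or self.t0 < 0:
            raise ValueError("DDM parameters out of range")


@dataclass
class ConditionSpec:
    """Condition-level criterion manipulation."""

    a_mult: float = 1.0
    t0_shift: float = 0.0
    time_base: str = "offset"

    def __post_init__(self):
        if self.a_mult <= 0:
            raise ValueError("threshold multiplier must be positive")


# instruction-style defaults: accuracy emphasis raises the criterion,
# speed emphasis lowers it
DEFAULT_CONDITIONS = {"combined": ConditionSpec(a_mult=1.0)}
INSTRUCTION_CONDITIONS = {
    "accuracy": ConditionSpec(a_mult=1.5),
    "combined": ConditionSpec(a_mult=1.0),
    "speed": ConditionSpec(a_mult=0.7),
}


@dataclass
class GeneratorConfig:
    """Ground-truth cohort and design description.

    Per-participant Weber fractions and response thresholds are drawn from
    truncated normal distributions; thresholds are shared across conditions
    up to the condition multiplier.  Defaults mirror a 400-trial
    dot-comparison session (ratios 0.5-0.9, 80 trials per ratio,
    numerosities 10-40) with a cohort w distribution centered near the
    adult range.
    """

    n_participants: int = 61
    experiment: str = "synthetic"
    w_mean: float = 0.6
    w_sd: float = 0.3
    w_bounds: tuple[float, float] = (0.1, 2.0)
    threshold_mean: float = 1.0
    threshold_sd: float = 0.0
    threshold_bounds: tuple[float, float] = (0.2, 5.0)
    conditions: Mapping[str, ConditionSpec] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )
    accuracy_model: str = "eq1_linear"
    beta_side: float = 0.0
    beta_size: float = 0.0
    beta_spacing: float = 0.0
    congruency_mix: float = 0.5
    visual_sd: float = 0.3
    ratios: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    n_min: int = 10
    n_max: int = 40
    trials_per_ratio: int = 80
    ddm: DDMParams = field(default_factory=DDMParams)
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conditions"] = {k: asdict(v) if isinstance(v, ConditionSpec) else v
                              for k, v in self.conditions.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "ddm" in data and isinstance(data["ddm"], dict):
            data["ddm"] = DDMParams(**data["ddm"])
        if "conditions" in data:
            data["conditions"] = {
                k: ConditionSpec(**v) if isinstance(v, dict) else v
                for k, v in data["conditions"].items()
            }
        for key in ("w_bounds", "threshold_bounds", "ratios"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _truncated_normal(
    mean: float, sd: float, bounds: tuple[float, float], size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, *bounds)))
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        ok = (draw >= bounds[0]) & (draw <= bounds[1])
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def generate_visual_features(
    items: pd.DataFrame, congruency_mix: float = 0.5, visual_sd: float = 0.3,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Draw DeWind-style visual log-ratios for an item table.

    Four component log-ratios (item surface area, total surface area, field
    area, sparsity) are drawn with magnitude ~ |N(0, visual_sd)| each;
    ``log2_r_size = log2 r_ISA + log2 r_TSA`` and ``log2_r_spacing = log2
    r_FA + log2 r_sparsity``.  With probability ``congruency_mix`` the
    size/spacing cues point toward the more numerous side (congruent trial),
    otherwise away from it; at 0.5 the visual signs are uncorrelated with
    the numerical sign.
    """
    if not 0.0 <= congruency_mix <= 1.0:
        raise ValueError("congruency_mix must lie in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = len(items)
    num_sign = np.sign(
        np.log2(items["n_right"].to_numpy(dtype=float) / items["n_left"].to_numpy(dtype=float))
    )
    congruent = rng.random(n) < congruency_mix
    sign = np.where(congruent, num_sign, -num_sign)
    comps = np.abs(rng.normal(0.0, visual_sd, size=(n, 4)))
    out = items.copy()
    out["log2_r_size"] = sign * (comps[:, 0] + comps[:, 1])
    out["log2_r_spacing"] = sign * (comps[:, 2] + comps[:, 3])
    return out


def ddm_sample(
    drift, params: DDMParams, rng: np.random.Generator | int = 0,
    a: float | np.ndarray | None = None,
):
    """Simulate first passage of drift-diffusion walkers.

    Euler-Maruyama walk from a/2 between absorbing bounds 0 and a, step
    ``v dt + s sqrt(dt) N(0,1)``, with a Brownian-bridge correction for
    boundary crossings inside a step (without it the discrete walk
    overshoots the bounds and biases choice probabilities upward).  Walkers
    still alive at ``max_time`` are restarted (and counted); returns
    ``(upper, decision_time_s, n_restarts)`` with ``upper`` True when the
    upper bound was hit.  ``drift`` may be a vector; ``a`` overrides the
    threshold per walker.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    v = np.atleast_1d(np.asarray(drift, dtype=float))
    n = len(v)
    a_vec = np.full(n, params.a) if a is None else np.broadcast_to(
        np.asarray(a, dtype=float), (n,)
    ).copy()
    x = a_vec / 2.0
    t = np.zeros(n)
    upper = np.zeros(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    sqdt = params.s * np.sqrt(params.dt)
    restarts = 0
    max_steps = int(params.max_time / params.dt)
    steps_alive = np.zeros(n, dtype=int)
    var_dt = params.s**2 * params.dt
    while not done.all():
        alive = np.flatnonzero(~done)
        x_old = x[alive].copy()
        x[alive] += v[alive] * params.dt + sqdt * rng.standard_normal(len(alive))
        t[alive] += params.dt
        steps_alive[alive] += 1
        x_new = x[alive]
        a_al = a_vec[alive]
        crossed_up = x_new >= a_al
        crossed_lo = (x_new <= 0.0) & ~crossed_up
        inside = ~crossed_up & ~crossed_lo
        if inside.any():
            # Brownian-bridge probability of touching a bound mid-step
            p_up = np.exp(-2.0 * (a_al[inside] - x_old[inside])
                          * (a_al[inside] - x_new[inside]) / var_dt)
            p_lo = np.exp(-2.0 * x_old[inside] * x_new[inside] / var_dt)
            u = rng.random(int(inside.sum()))
            bridge_up = u < p_up
            bridge_lo = ~bridge_up & (u < p_up + p_lo)
            crossed_up[inside] |= bridge_up
            crossed_lo[inside] |= bridge_lo
        hit_up = alive[crossed_up]
        hit_lo = alive[crossed_lo]
        upper[hit_up] = True
        done[hit_up] = True
        done[hit_lo] = True
        stuck = alive[steps_alive[alive] >= max_steps]
        if len(stuck):
            restarts += len(stuck)
            x[stuck] = a_vec[stuck] / 2.0
            t[stuck] = 0.0
            steps_alive[stuck] = 0
    if np.isscalar(drift):
        return bool(upper[0]), float(t[0]), restarts
    return upper, t, restarts


def generate_experiment(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a full multi-condition experiment via the diffusion responder.

    The item set is built once and shared by all participants (order
    reshuffled per participant x condition).  Per participant, a Weber
    fraction and a baseline threshold are drawn; per trial, the drift is
    ``sign(log2 r_num) * v_scale * |log2 r_num| / w`` and choice/RT come
    from :func:`ddm_sample` at the condition-scaled threshold.  Deterministic
    given ``config.seed``.
    """
    master = np.random.SeedSequence(config.seed)
    ss_items, ss_visual, ss_cohort, ss_trials = master.spawn(4)
    items = build_item_set(
        config.ratios, config.n_min, config.n_max, config.trials_per_ratio,
        seed=np.random.default_rng(ss_items),
    )
    items = generate_visual_features(
        items, config.congruency_mix, config.visual_sd,
        rng=np.random.default_rng(ss_visual),
    )
    rng_cohort = np.random.default_rng(ss_cohort)
    w = _truncated_normal(
        config.w_mean, config.w_sd, config.w_bounds, config.n_participants, rng_cohort
    )
    a_base = _truncated_normal(
        config.threshold_mean, config.threshold_sd, config.threshold_bounds,
        config.n_participants, rng_cohort,
    )
    rng_trials = np.random.default_rng(ss_trials)

    log2_rnum = np.log2(
        items["n_right"].to_numpy(dtype=float) / items["n_left"].to_numpy(dtype=float)
    )
    frames = []
    for p_idx in range(config.n_participants):
        pid = f"P{p_idx + 1:03d}"
        for cond_name, spec in config.conditions.items():
            order = rng_trials.permutation(len(items))
            block = items.iloc[order].reset_index(drop=True)
            drift = (
                np.sign(log2_rnum[order])
                * config.ddm.v_scale
                * np.abs(log2_rnum[order])
                / w[p_idx]
            )
            chose_right, dt_s, _ = ddm_sample(
                drift, config.ddm, rng_trials, a=a_base[p_idx] * spec.a_mult
            )
            t0 = max(0.0, config.ddm.t0 + spec.t0_shift)
            larger_right = block["n_right"].to_numpy() > block["n_left"].to_numpy()
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "experiment": config.experiment,
                        "condition": cond_name,
                        "n_left": block["n_left"],
                        "n_right": block["n_right"],
                        "response_side": np.where(chose_right, "right", "left"),
                        "correct": chose_right == larger_right,
                        "rt_ms": (dt_s + t0) * 1000.0,
                        "log2_r_size": block["log2_r_size"],
                        "log2_r_spacing": block["log2_r_spacing"],
                        "rt_time_base": spec.time_base,
                        "true_w": w[p_idx],
                        "true_threshold": a_base[p_idx] * spec.a_mult,
                    }
                )
            )
    return derive_covariates(
        pd.concat(frames, ignore_index=True), design_ratios=config.ratios
    )


def generate_accuracy_only(
    config: GeneratorConfig, model: str | None = None
) -> pd.DataFrame:
    """Generate choice-only trials (rt_ms NaN) from an accuracy model.

    ``model`` is one of ``eq1_linear``, ``eq3_log``, ``eq4_modlog``
    (defaults to ``config.accuracy_model``).  Responses are Bernoulli draws
    from the model's choose-right probability; for the linear model, the
    correct side is chosen with the Eq-1 accuracy (side-symmetric).
    """
    model = model or config.accuracy_model
    if model not in ("eq1_linear", "eq3_log", "eq4_modlog"):
        raise ValueError(f"unknown accuracy model {model!r}")
    master = np.random.SeedSequence(config.seed)
    ss_items, ss_visual, ss_cohort, ss_trials = master.spawn(4)
    items = build_item_set(
        config.ratios, config.n_min, config.n_max, config.trials_per_ratio,
        seed=np.random.default_rng(ss_items),
    )
    items = generate_visual_features(
        items, config.congruency_mix, config.visual_sd,
        rng=np.random.default_rng(ss_visual),
    )
    rng_cohort = np.random.default_rng(ss_cohort)
    w = _truncated_normal(
        config.w_mean, config.w_sd, config.w_bounds, config.n_participants, rng_cohort
    )
    rng = np.random.default_rng(ss_trials)

    n_left = items["n_left"].to_numpy(dtype=float)
    n_right = items["n_right"].to_numpy(dtype=float)
    r_num = n_right / n_left
    larger_right = n_right > n_left
    frames = []
    for p_idx in range(config.n_participants):
        pid = f"P{p_idx + 1:03d}"
        if model == "eq1_linear":
            p_correct = predict_accuracy_linear(np.maximum(r_num, 1 / r_num), w[p_idx])
            correct = rng.random(len(items)) < p_correct
            chose_right = np.where(correct, larger_right, ~larger_right)
        else:
            if model == "eq3_log":
                p_right = predict_choose_right_log(r_num, w[p_idx])
            else:
                beta_num = 1.0 / (np.sqrt(2.0) * w[p_idx])
                p_right = predict_choose_right_modlog(
                    r_num,
                    items["log2_r_size"].to_numpy(),
                    items["log2_r_spacing"].to_numpy(),
                    config.beta_side,
                    beta_num,
                    config.beta_size,
                    config.beta_spacing,
                )
            chose_right = rng.random(len(items)) < p_right
            correct = chose_right == larger_right
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "experiment": config.experiment,
                    "condition": "accuracy_only",
                    "n_left": items["n_left"],
                    "n_right": items["n_right"],
                    "response_side": np.where(chose_right, "right", "left"),
                    "correct": correct,
                    "rt_ms": np.nan,
                    "log2_r_size": items["log2_r_size"],
                    "log2_r_spacing": items["log2_r_spacing"],
                    "true_w": w[p_idx],
                }
            )
        )
    return derive_covariates(
        pd.concat(frames, ignore_index=True), design_ratios=config.ratios
    )
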