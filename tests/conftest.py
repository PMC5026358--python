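"""Shared fixtures: small synthetic cohorts and item sets."""

import numpy as np
import pandas as pd
import pytest

from ansacuity.synthetic import GeneratorConfig, generate_accuracy_only, generate_experiment
from ansacuity.trialdata import build_item_set, derive_covariates

DESIGN_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9)


def make_bernoulli_trials(
    p_correct_fn, items: pd.DataFrame, rng: np.random.Generator,
    participant_id: str = "P001", rt_fn=None,
) -> pd.DataFrame:
    """Trials with correctness drawn from p_correct_fn(ratio_R) per item."""
    n_left = items["n_left"].to_numpy()
    n_right = items["n_right"].to_numpy()
    ratio = np.minimum(n_left, n_right) / np.maximum(n_left, n_right)
    p = p_correct_fn(ratio)
    correct = rng.random(len(items)) < p
    larger_right = n_right > n_left
    chose_right = np.where(correct, larger_right, ~larger_right)
    rt = rt_fn(ratio, rng) if rt_fn is not None else np.full(len(items), 500.0)
    return derive_covariates(
        pd.DataFrame(
            {
                "participant_id": participant_id,
                "experiment": "synthetic",
                "condition": "c",
                "n_left": n_left,
                "n_right": n_right,
                "response_side": np.where(chose_right, "right", "left"),
                "correct": correct,
                "rt_ms": rt,
            }
        ),
        design_ratios=DESIGN_RATIOS,
    )


@pytest.fixture(scope="session")
def item_set() -> pd.DataFrame:
    return build_item_set(DESIGN_RATIOS, 10, 40, trials_per_ratio=80, seed=11)


@pytest.fixture(scope="session")
def small_item_set() -> pd.DataFrame:
    return build_item_set(DESIGN_RATIOS, 10, 40, trials_per_ratio=20, seed=12)


@pytest.fixture(scope="session")
def accuracy_cohort() -> pd.DataFrame:
    """20 participants, heterogeneous w, accuracy-only linear-model responses."""
    cfg = GeneratorConfig(n_participants=20, w_mean=0.6, w_sd=0.3, seed=101)
    return generate_accuracy_only(cfg, "eq1_linear")


@pytest.fixture(scope="session")
def ddm_cohort() -> pd.DataFrame:
    """15 participants, diffusion responder, heterogeneous w, 100 trials."""
    cfg = GeneratorConfig(
        n_participants=15, w_mean=0.6, w_sd=0.3, trials_per_ratio=20, seed=202
    )
    return generate_experiment(cfg)
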