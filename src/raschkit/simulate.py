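"""Seeded simulation of dichotomous Rasch response data.

The generator draws person abilities from a normal distribution, fills the
persons x items matrix with independent Bernoulli responses at the model
probabilities, and attaches random two-level group labels.  The packaged
study design is 300 simulees from N(0, 1) answering 10 items whose
difficulties span -2.43 to 2.47 logits, plus one appended all-correct
responder ("GPT301") whose extreme score exercises the adjustment path
downstream.  One seed governs abilities, responses and labels in a fixed
draw order, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ResponseMatrix
from .model import dichotomous_probability

__all__ = ["STUDY_DIFFICULTIES", "SimulationConfig", "simulate_responses",
           "build_study_dataset"]

#: the ten study item difficulties (logits), easiest to hardest
STUDY_DIFFICULTIES = (
    -2.43, -1.78, -1.48, -0.64, -0.1, 0.33, 0.59, 1.34, 1.7, 2.47,
)

#: id given to the appended perfect responder
PERFECT_RESPONDER_ID = "GPT301"


@dataclass
class SimulationConfig:
    """Study design parameters for the response generator."""

    n_persons: int = 300
    difficulties: tuple = STUDY_DIFFICULTIES
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    group_probability: float = 0.5
    seed: int = 0
    append_perfect_responder: bool = False
    group_labels: tuple = ("Female", "Male")

    def __post_init__(self) -> None:
        if self.ability_sd <= 0:
            raise ValueError("ability_sd must be positive")
        if not 0.0 <= self.group_probability <= 1.0:
            raise ValueError("group_probability must lie in [0, 1]")
        if len(self.difficulties) == 0:
            raise ValueError("difficulties must be non-empty")
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")


def simulate_responses(config: SimulationConfig) -> ResponseMatrix:
    """Draw a persons x items 0/1 matrix under the Rasch model.

    Abilities ~ Normal(mean, sd); cell (n, i) is Bernoulli with success
    probability P(theta_n, delta_i); group labels are iid Bernoulli with
    ``group_probability`` for the first label.  True abilities ride along
    on the returned matrix for parameter-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    delta = np.asarray(config.difficulties, dtype=float)
    theta = rng.normal(config.ability_mean, config.ability_sd, config.n_persons)
    p = dichotomous_probability(theta[:, None], delta[None, :])
    scores = (rng.random(p.shape) < p).astype(float)
    lab1, lab2 = config.group_labels
    groups = np.where(
        rng.random(config.n_persons) < config.group_probability, lab1, lab2
    ).tolist()
    ids = [f"P{i + 1:03d}" for i in range(config.n_persons)]
    return ResponseMatrix(scores, ids, [f"item_{i + 1}" for i in range(delta.size)],
                          groups, true_thetas=theta)


def build_study_dataset(config: SimulationConfig) -> ResponseMatrix:
    """The packaged study matrix: simulees plus one all-correct responder.

    Appends a person with every response correct (raw score L, an extreme
    score by construction) and a group label drawn from the same stream.
    """
    if not config.append_perfect_responder:
        raise ValueError("build_study_dataset requires append_perfect_responder=True")
    base = simulate_responses(config)
    rng = np.random.default_rng([config.seed, 10007])  # separate label stream
    lab1, lab2 = config.group_labels
    label = lab1 if rng.random() < config.group_probability else lab2
    scores = np.vstack([base.scores, np.ones((1, base.n_items))])
    return ResponseMatrix(
        scores,
        base.person_ids + [PERFECT_RESPONDER_ID],
        base.item_ids,
        (base.groups or []) + [label],
        true_thetas=np.append(base.true_thetas, np.nan),
    )
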