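"""Rasch model mathematics.

The dichotomous Rasch model places person ability ``theta`` and item
difficulty ``delta`` on a common logit (natural-log-odds) scale and models
the probability of a correct response as

    P = exp(theta - delta) / (1 + exp(theta - delta))

The rating-scale model (RSM) generalises this to ordered response
categories sharing one set of step thresholds ``tau``; with two categories
it collapses exactly to the dichotomous model.  Everything here is pure,
vectorised math consumed by the estimation and diagnostic layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "PersonMeasure",
    "RSMParameters",
    "dichotomous_probability",
    "rsm_category_probability",
    "response_variance",
    "person_se",
]


@dataclass
class ItemParameters:
    """Calibrated parameters and diagnostics for one item.

    ``difficulty`` and ``se`` are in logits; the mean-square fit statistics
    are dimensionless with expectation ~1 under the model.  Fit fields are
    NaN until the fit layer fills them in.
    """

    item_id: str
    difficulty: float
    se: float
    infit_mnsq: float = np.nan
    outfit_mnsq: float = np.nan
    icc_fit_p: float = np.nan


@dataclass
class PersonMeasure:
    """Ability estimate and diagnostics for one person.

    ``theta`` is the (possibly extreme-score-adjusted) maximum-likelihood
    ability in logits, ``raw_score`` the observed count of correct
    responses over administered items.
    """

    person_id: str
    theta: float
    se: float
    raw_score: float
    infit_mnsq: float = np.nan
    outfit_mnsq: float = np.nan
    grade: str | None = None
    group: str | None = None


@dataclass
class RSMParameters:
    """Rating-scale item: one difficulty plus ordered step thresholds.

    ``thresholds`` holds tau_1..tau_{m-1} for m response categories.  With
    m = 2 the single threshold is 0 and the category-1 probability equals
    the dichotomous model exactly.
    """

    difficulty: float
    thresholds: list[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self) -> None:
        tau = np.asarray(self.thresholds, dtype=float)
        if tau.size == 0:
            raise ValueError("RSM needs at least one threshold (>= 2 categories)")
        if np.any(np.diff(tau) < 0):
            raise ValueError("RSM thresholds must be ordered")
        self.thresholds = list(tau)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


def _check_finite(**named: object) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite, got {value!r}")


def dichotomous_probability(theta, delta):
    """P(correct) = exp(theta-delta)/(1+exp(theta-delta)).

    Evaluated through :func:`scipy.special.expit`, which is overflow-safe
    for arbitrarily large |theta - delta|.  Accepts scalars or broadcastable
    arrays and returns the broadcast result.
    """
    _check_finite(theta=theta, delta=delta)
    return expit(np.asarray(theta, dtype=float) - np.asarray(delta, dtype=float))


def rsm_category_probability(theta, params: RSMParameters, category: int):
    """Probability of responding in ``category`` under the rating-scale model.

    Uses the standard cumulative-numerator form: the unnormalised weight of
    category k is exp(sum_{j<=k} (theta - delta - tau_j)) with the empty sum
    for k = 0, normalised over all m categories.  Probabilities sum to one;
    with two categories and tau = [0] the result equals
    :func:`dichotomous_probability` for category 1.
    """
    _check_finite(theta=theta, delta=params.difficulty)
    m = params.n_categories
    if not 0 <= category <= m - 1:
        raise ValueError(f"category {category} out of range for {m} categories")
    theta = np.asarray(theta, dtype=float)
    tau = np.asarray(params.thresholds, dtype=float)
    # log-weights per category, shape (..., m); log-sum-exp for stability
    steps = theta[..., None] - params.difficulty - tau  # (..., m-1)
    logw = np.concatenate(
        [np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1
    )
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    probs = w / w.sum(axis=-1, keepdims=True)
    out = probs[..., category]
    return float(out) if out.ndim == 0 else out


def response_variance(theta, delta):
    """Bernoulli variance P*Q of a response; also dP/dtheta.

    The derivative of the dichotomous response probability with respect to
    ability equals the response variance, which is what makes the Newton
    step of the score equation an information-weighted update.
    """
    p = dichotomous_probability(theta, delta)
    return p * (1.0 - p)


def person_se(theta, difficulties) -> float:
    """Ability standard error: reciprocal square root of total information.

    SE(theta) = 1 / sqrt(sum_i P_i Q_i) over the administered items; adding
    items can only shrink it.
    """
    difficulties = np.asarray(difficulties, dtype=float)
    if difficulties.size == 0:
        raise ValueError("person_se needs at least one administered item")
    info = response_variance(theta, difficulties).sum()
    return float(1.0 / np.sqrt(info))
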