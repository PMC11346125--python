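"""Joint maximum likelihood (JMLE) calibration of the dichotomous Rasch model.

Raw scores are sufficient statistics, so estimation reduces to solving
score equations: a person's ability solves ``sum_i P_i(theta) = r`` over
administered items, and an item's difficulty solves the dual equation over
persons.  Both are solved by damped Newton-Raphson, where the derivative of
the expected score is the summed response variance (the test information),
giving the update ``d_theta = (r - sum P) / sum PQ``.

The joint scheme alternates a full person solve with one damped item update
per cycle, re-centres item difficulties to mean zero (the identification
convention), and stops when the largest parameter change falls below a
tolerance.  Zero and perfect raw scores have no finite ML solution; they
are pulled inside the admissible range by a fractional score adjustment
(default 0.25 score points) before solving.  JMLE difficulties are
inconsistent at fixed test length; the classic (L-1)/L shrinkage is applied
by default to correct the bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ResponseMatrix
from .model import PersonMeasure, person_se

__all__ = [
    "CalibrationResult",
    "adjust_extreme_scores",
    "estimate_person",
    "jmle_calibrate",
]

#: default fractional score-point adjustment for zero/perfect raw scores
DEFAULT_ADJUST = 0.25
#: largest Newton step accepted per iteration, in logits
MAX_STEP = 1.0


@dataclass
class CalibrationResult:
    """Output of a joint calibration.

    ``items`` has one row per retained item (item_id, difficulty, se, fit
    columns); ``persons`` one row per person (person_id, theta, se,
    raw_score, fit columns, grade, group).  ``log`` records the largest
    parameter change per outer cycle.
    """

    items: pd.DataFrame
    persons: pd.DataFrame
    n_iterations: int
    converged: bool
    log: list[float] = field(default_factory=list)
    dropped_items: list[str] = field(default_factory=list)

    @property
    def difficulties(self) -> np.ndarray:
        return self.items["difficulty"].to_numpy()

    @property
    def thetas(self) -> np.ndarray:
        return self.persons["theta"].to_numpy()


def adjust_extreme_scores(raw: float, L: int, adjust: float = DEFAULT_ADJUST) -> float:
    """Pull extreme raw scores (0 or L) inside the open interval (0, L).

    Returns ``raw + adjust`` for a zero score, ``raw - adjust`` for a
    perfect score, and ``raw`` unchanged otherwise.  Required because the
    ML ability for an extreme score is infinite.
    """
    if not 0.0 < adjust < 1.0:
        raise ValueError(f"adjust must lie in (0, 1), got {adjust}")
    if not 0 <= raw <= L:
        raise ValueError(f"raw score {raw} outside [0, {L}]")
    if raw == 0:
        return raw + adjust
    if raw == L:
        return raw - adjust
    return float(raw)


def _solve_theta(
    r_eff: np.ndarray,
    deltas: np.ndarray,
    mask: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    theta0: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised damped Newton solve of sum_i P(theta_n, delta_i) = r_n.

    ``mask`` (persons x items bool) restricts each person's sum to
    administered items.  The score function is strictly increasing in
    theta, so the damped Newton iteration converges from any start.
    """
    n = r_eff.shape[0]
    theta = np.zeros(n) if theta0 is None else theta0.astype(float).copy()
    m = np.ones((n, deltas.size), dtype=bool) if mask is None else mask
    for _ in range(max_iter):
        p = expit(theta[:, None] - deltas[None, :])
        expected = np.where(m, p, 0.0).sum(axis=1)
        info = np.where(m, p * (1.0 - p), 0.0).sum(axis=1)
        step = (r_eff - expected) / np.maximum(info, 1e-12)
        step = np.clip(step, -MAX_STEP, MAX_STEP)
        theta += step
        if np.max(np.abs(step)) < tol:
            break
    return theta


def estimate_person(
    responses,
    difficulties,
    adjust_extreme: float = DEFAULT_ADJUST,
    person_id: str = "person",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PersonMeasure:
    """Ability estimate against anchored item difficulties.

    Solves the score equation by damped Newton-Raphson after replacing an
    extreme raw score with its adjusted value.  Missing responses (NaN) are
    excluded cell-wise.  The SE is the reciprocal root of the information
    at the solution over the administered items.
    """
    responses = np.asarray(responses, dtype=float)
    difficulties = np.asarray(difficulties, dtype=float)
    if responses.shape != difficulties.shape:
        raise ValueError("responses and difficulties must align")
    present = ~np.isnan(responses)
    if not present.any():
        raise ValueError("all responses missing; ability is undefined")
    raw = float(np.nansum(responses))
    L = int(present.sum())
    r_eff = adjust_extreme_scores(raw, L, adjust_extreme)
    theta = _solve_theta(
        np.array([r_eff]), difficulties[present], tol=tol, max_iter=max_iter
    )[0]
    return PersonMeasure(
        person_id=person_id,
        theta=float(theta),
        se=person_se(theta, difficulties[present]),
        raw_score=raw,
    )


def jmle_calibrate(
    data: ResponseMatrix,
    tol: float = 1e-4,
    max_iter: int = 100,
    bias_correction: bool = True,
    adjust_extreme: float = DEFAULT_ADJUST,
) -> CalibrationResult:
    """Joint Newton-Raphson calibration of item difficulties and abilities.

    Items answered all-correct or all-incorrect by every responder carry no
    difficulty information and are dropped with a warning.  Persons with
    extreme raw scores are excluded from the item step (they carry no
    item-contrast information) and scored afterwards against the final
    difficulties at their adjusted raw scores.

    At convergence every non-extreme person's expected score matches the
    observed raw score, and dually for items (the score-matching property
    of Rasch ML).  Difficulties are mean-centred each cycle; with
    ``bias_correction`` the final centred difficulties are shrunk by
    (L-1)/L, the standard finite-test JMLE correction.
    """
    if data.n_persons < 2 or data.n_items < 2:
        raise ValueError("calibration needs at least 2 persons and 2 items")

    # drop degenerate items
    mask = data.mask
    col_scores = data.raw_item_scores()
    col_n = mask.sum(axis=0)
    bad = np.where((col_scores == 0) | (col_scores == col_n))[0]
    dropped = [data.item_ids[j] for j in bad]
    if dropped:
        warnings.warn(
            f"items with extreme scores dropped from calibration: {dropped}",
            stacklevel=2,
        )
        data = data.drop_items(bad)
        mask = data.mask

    L = data.n_items
    raw = data.raw_person_scores()
    n_admin = data.items_administered()
    extreme = (raw == 0) | (raw == n_admin)
    interior = ~extreme

    scores = np.nan_to_num(data.scores, nan=0.0)
    sub_mask = mask[interior]
    sub_scores = scores[interior]
    r_int = raw[interior]

    # logit starting values from observed proportions
    item_obs = np.where(sub_mask, sub_scores, 0.0).sum(axis=0)
    item_n = sub_mask.sum(axis=0)
    frac = np.clip(item_obs / np.maximum(item_n, 1), 1e-3, 1 - 1e-3)
    deltas = np.log((1 - frac) / frac)
    deltas -= deltas.mean()
    theta = np.log(
        np.clip(r_int, 0.25, None) / np.clip(n_admin[interior] - r_int, 0.25, None)
    )

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_new = _solve_theta(r_int, deltas, sub_mask, theta0=theta)
        p = expit(theta_new[:, None] - deltas[None, :])
        expected_item = np.where(sub_mask, p, 0.0).sum(axis=0)
        info_item = np.where(sub_mask, p * (1.0 - p), 0.0).sum(axis=0)
        step = (expected_item - item_obs) / np.maximum(info_item, 1e-12)
        step = np.clip(step, -MAX_STEP, MAX_STEP)
        deltas_new = deltas + step
        deltas_new -= deltas_new.mean()
        change = max(
            np.max(np.abs(deltas_new - deltas)), np.max(np.abs(theta_new - theta))
        )
        history.append(float(change))
        deltas, theta = deltas_new, theta_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"JMLE did not converge in {max_iter} iterations "
            f"(last change {history[-1]:.2e}); returning best iterate",
            stacklevel=2,
        )

    if bias_correction and L > 1:
        deltas = deltas * (L - 1) / L

    # final person measures for everyone, extremes at adjusted scores
    r_eff = np.array(
        [adjust_extreme_scores(r, int(n), adjust_extreme) for r, n in zip(raw, n_admin)]
    )
    theta_all = _solve_theta(r_eff, deltas, mask)
    p_all = expit(theta_all[:, None] - deltas[None, :])
    info_person = np.where(mask, p_all * (1 - p_all), 0.0).sum(axis=1)
    info_item_f = np.where(mask[interior], (p_all * (1 - p_all))[interior], 0.0).sum(
        axis=0
    )

    items = pd.DataFrame(
        {
            "item_id": data.item_ids,
            "difficulty": deltas,
            "se": 1.0 / np.sqrt(np.maximum(info_item_f, 1e-12)),
            "infit_mnsq": np.nan,
            "outfit_mnsq": np.nan,
            "icc_fit_p": np.nan,
        }
    )
    persons = pd.DataFrame(
        {
            "person_id": data.person_ids,
            "theta": theta_all,
            "se": 1.0 / np.sqrt(np.maximum(info_person, 1e-12)),
            "raw_score": raw,
            "infit_mnsq": np.nan,
            "outfit_mnsq": np.nan,
            "grade": pd.NA,
            "group": data.groups if data.groups is not None else pd.NA,
        }
    )
    return CalibrationResult(
        items=items,
        persons=persons,
        n_iterations=it,
        converged=converged,
        log=history,
        dropped_items=dropped,
    )
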