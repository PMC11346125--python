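"""Residual-based fit diagnostics for a Rasch calibration.

Each observed cell x_ni has model expectation P_ni and variance
W_ni = P_ni Q_ni, giving the standardized residual
z_ni = (x_ni - P_ni) / sqrt(W_ni).  From these come the two classic
mean-square statistics per item (or person) margin:

* outfit — the unweighted mean of z^2, sensitive to unexpected responses
  far from the margin's location;
* infit  — the information-weighted form sum (x-P)^2 / sum W, sensitive to
  unexpected patterns near the location.

Both have expectation ~1 when the data fit; items are commonly screened at
infit < 1.5 and aberrant persons at outfit < 2.0.  The chi-square item-fit
test bins persons into ability strata and compares observed to expected
stratum mean scores along the item characteristic curve (ICC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import ResponseMatrix
from .estimation import CalibrationResult
from .model import dichotomous_probability

__all__ = [
    "ResidualTable",
    "IccFitResult",
    "standardized_residuals",
    "infit_outfit",
    "icc_fit",
    "add_fit_statistics",
]


@dataclass
class ResidualTable:
    """Cellwise observed/expected/variance/z arrays (NaN where missing)."""

    observed: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    person_ids: list[str]
    item_ids: list[str]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.observed)


@dataclass
class IccFitResult:
    """Ability-stratum chi-square fit for one item.

    ``strata`` rows are (mean_theta, n, observed_mean, expected_mean); the
    statistic sums the squared stratum-mean deviations over the sampling
    variance of the stratum mean.
    """

    item_id: str
    strata: pd.DataFrame
    chisq: float
    df: int
    p: float
    curve: pd.DataFrame  # theta-grid ICC for plotting


def standardized_residuals(
    data: ResponseMatrix, result: CalibrationResult
) -> ResidualTable:
    """z_ni = (observed - expected) / sqrt(P_ni Q_ni) per non-missing cell."""
    if data.n_items != len(result.items) or data.n_persons != len(result.persons):
        raise ValueError("response matrix and calibration result do not align")
    theta = result.thetas
    delta = result.difficulties
    expected = dichotomous_probability(theta[:, None], delta[None, :])
    variance = expected * (1.0 - expected)
    observed = data.scores
    z = (observed - expected) / np.sqrt(variance)
    missing = np.isnan(observed)
    return ResidualTable(
        observed=observed,
        expected=np.where(missing, np.nan, expected),
        variance=np.where(missing, np.nan, variance),
        z=z,
        person_ids=list(data.person_ids),
        item_ids=list(data.item_ids),
    )


def infit_outfit(residuals: ResidualTable, margin: str = "item") -> pd.DataFrame:
    """Infit/outfit mean squares along one margin.

    outfit = mean(z^2); infit = sum (obs-exp)^2 / sum var.  Returns one row
    per item (``margin='item'``) or per person (``margin='person'``).
    """
    if margin not in ("item", "person"):
        raise ValueError("margin must be 'item' or 'person'")
    axis = 0 if margin == "item" else 1
    labels = residuals.item_ids if margin == "item" else residuals.person_ids
    counts = residuals.mask.sum(axis=axis)
    if np.any(counts < 2):
        raise ValueError(f"a {margin} margin has fewer than 2 observed cells")
    with np.errstate(invalid="ignore"):
        outfit = np.nanmean(residuals.z**2, axis=axis)
        sq = (residuals.observed - residuals.expected) ** 2
        infit = np.nansum(sq, axis=axis) / np.nansum(residuals.variance, axis=axis)
    return pd.DataFrame(
        {margin + "_id": labels, "infit_mnsq": infit, "outfit_mnsq": outfit}
    )


def icc_fit(
    item_id: str,
    data: ResponseMatrix,
    result: CalibrationResult,
    n_strata: int = 5,
) -> IccFitResult:
    """Chi-square fit of one item's observed scores to its ICC.

    Persons are split into ``n_strata`` equal-count ability class intervals
    on the estimated theta.  Per stratum the observed mean item score is
    compared with the model-expected mean; the statistic is
    sum_s (obs_s - exp_s)^2 / Var(mean_s) with Var(mean_s) =
    sum_n P_n Q_n / n_s^2, referred to chi-square with n_strata - 1 df.
    Empty strata are merged into a neighbour with a warning.
    """
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    j = list(data.item_ids).index(item_id)
    delta = float(result.difficulties[j])
    obs_col = data.scores[:, j]
    present = ~np.isnan(obs_col)
    theta = result.thetas[present]
    obs = obs_col[present]

    edges = np.quantile(theta, np.linspace(0, 1, n_strata + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.clip(np.searchsorted(edges, theta, side="right") - 1, 0, n_strata - 1)

    rows, chisq = [], 0.0
    merged = 0
    for s in range(n_strata):
        sel = idx == s
        n_s = int(sel.sum())
        if n_s == 0:
            merged += 1
            continue
        p_s = dichotomous_probability(theta[sel], delta)
        exp_mean = float(p_s.mean())
        obs_mean = float(obs[sel].mean())
        var_mean = float((p_s * (1 - p_s)).sum()) / n_s**2
        chisq += (obs_mean - exp_mean) ** 2 / max(var_mean, 1e-12)
        rows.append((float(theta[sel].mean()), n_s, obs_mean, exp_mean))
    if merged:
        warnings.warn(f"{merged} empty strata merged for item {item_id}", stacklevel=2)
    df = max(len(rows) - 1, 1)
    p = float(chi2.sf(chisq, df))
    grid = np.linspace(theta.min() - 1, theta.max() + 1, 101)
    curve = pd.DataFrame(
        {"theta": grid, "expected": dichotomous_probability(grid, delta)}
    )
    strata = pd.DataFrame(
        rows, columns=["mean_theta", "n", "observed_mean", "expected_mean"]
    )
    return IccFitResult(item_id=item_id, strata=strata, chisq=float(chisq), df=df, p=p,
                        curve=curve)


def add_fit_statistics(
    data: ResponseMatrix, result: CalibrationResult, n_strata: int = 5
) -> CalibrationResult:
    """Fill the fit columns of a calibration result in place (and return it)."""
    res = standardized_residuals(data, result)
    ifit = infit_outfit(res, "item")
    pfit = infit_outfit(res, "person")
    result.items["infit_mnsq"] = ifit["infit_mnsq"].to_numpy()
    result.items["outfit_mnsq"] = ifit["outfit_mnsq"].to_numpy()
    result.persons["infit_mnsq"] = pfit["infit_mnsq"].to_numpy()
    result.persons["outfit_mnsq"] = pfit["outfit_mnsq"].to_numpy()
    result.items["icc_fit_p"] = [
        icc_fit(iid, data, result, n_strata).p for iid in data.item_ids
    ]
    return result
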