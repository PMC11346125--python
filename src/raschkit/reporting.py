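"""Grades, KIDMAP and Wright-map data products, group tests, and reports.

Person measures are banded into five grades on the logit scale (default
cut-points 3.0, 1.5, -1.5, -3.0 giving A..E, upper-exclusive).  A KIDMAP is
a single-person diagnostic: each item's observed response is compared with
its model expectation at the person's ability, and standardized residuals
outside +/-2 mark unexpected responses.  The Wright map histograms the
person ability distribution against the item difficulty locations on the
shared logit axis.  Tables are the tested surface; SVG plots are rendered
from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseMatrix
from .dif import DIFResult, forest_table
from .estimation import CalibrationResult
from .model import PersonMeasure, dichotomous_probability

__all__ = [
    "GradeBands",
    "KidmapRecord",
    "assign_grade",
    "kidmap",
    "wright_map_data",
    "compare_groups",
    "write_reports",
]


@dataclass
class GradeBands:
    """Ordered ability cut-points (logits) defining the A..E grade bands.

    A band's threshold is exclusive from above: theta > 3.0 is A,
    1.5 < theta <= 3.0 is B, and so on down to theta <= -3.0 as E.
    """

    thresholds: tuple = (3.0, 1.5, -1.5, -3.0)
    labels: tuple = ("A", "B", "C", "D", "E")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need exactly one more label than thresholds")
        if np.any(np.diff(self.thresholds) >= 0):
            raise ValueError("thresholds must be strictly decreasing")


@dataclass
class KidmapRecord:
    """Per-item observed/expected/z diagnostics for one person.

    ``rows`` is sorted by item difficulty; ``quadrant`` classifies each
    item by correctness and |z| > 2 (expected vs unexpected).
    """

    person_id: str
    theta: float
    se: float
    outfit_mnsq: float
    rows: pd.DataFrame = field(repr=False)

    def quadrant_counts(self) -> dict:
        return self.rows["quadrant"].value_counts().to_dict()


def assign_grade(theta: float, bands: GradeBands | None = None) -> str:
    """Map an ability in logits to its grade band."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    bands = bands or GradeBands()
    for cut, label in zip(bands.thresholds, bands.labels):
        if theta > cut:
            return label
    return bands.labels[-1]


def kidmap(
    person: PersonMeasure,
    data: ResponseMatrix,
    items: pd.DataFrame,
) -> KidmapRecord:
    """Single-person diagnostic map against the calibrated items.

    For each administered item: expected = P(theta, delta), z = (obs -
    exp)/sqrt(PQ), and a quadrant label combining correctness with whether
    the response is unexpected (|z| > 2).  Outfit is the mean of z^2.
    """
    if person.person_id not in data.person_ids:
        raise ValueError(f"person {person.person_id!r} not in the response matrix")
    n = data.person_ids.index(person.person_id)
    obs = data.scores[n]
    delta = items["difficulty"].to_numpy()
    expected = dichotomous_probability(person.theta, delta)
    var = expected * (1 - expected)
    z = (obs - expected) / np.sqrt(var)
    correct = obs == 1
    unexpected = np.abs(z) > 2.0
    quadrant = np.where(
        correct,
        np.where(unexpected, "unexpected-correct", "expected-correct"),
        np.where(unexpected, "unexpected-incorrect", "expected-incorrect"),
    )
    rows = pd.DataFrame(
        {
            "item_id": items["item_id"],
            "difficulty": delta,
            "observed": obs,
            "expected": expected,
            "z": z,
            "quadrant": quadrant,
        }
    ).dropna(subset=["observed"])
    rows = rows.sort_values("difficulty", ignore_index=True)
    outfit = float(np.nanmean(z**2))
    return KidmapRecord(
        person_id=person.person_id,
        theta=person.theta,
        se=person.se,
        outfit_mnsq=outfit,
        rows=rows,
    )


def wright_map_data(
    persons: pd.DataFrame,
    items: pd.DataFrame,
    bin_width: float = 0.5,
    group_by: str | None = "group",
) -> dict:
    """Wright-map tables: theta histogram per group + item placements.

    Bins are half-open [lower, lower + width) on the logit axis shared with
    the item difficulty column.  Returns {'bins': DataFrame with one count
    column per group and 'total', 'items': difficulty placements}.
    """
    theta = persons["theta"].to_numpy()
    lo = np.floor(theta.min() / bin_width) * bin_width
    hi = np.ceil((theta.max() + 1e-9) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx = np.clip(np.floor((theta - lo) / bin_width).astype(int), 0, len(edges) - 2)
    table = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:]})
    counts = np.bincount(idx, minlength=len(edges) - 1)
    table["total"] = counts
    if group_by is not None and group_by in persons and persons[group_by].notna().any():
        for lv, sub in persons.groupby(group_by, observed=True):
            sidx = idx[persons.index.get_indexer(sub.index)]
            table[str(lv)] = np.bincount(sidx, minlength=len(edges) - 1)
    items_out = items[["item_id", "difficulty"]].copy()
    return {"bins": table, "items": items_out}


def compare_groups(persons: pd.DataFrame, factor: str = "group") -> dict:
    """One-way ANOVA of person measures across the levels of ``factor``.

    Returns F, p, degrees of freedom, and per-group means; for a two-level
    factor also the equivalent t statistic (F = t^2).
    """
    if factor not in persons:
        raise ValueError(f"no column {factor!r} in the persons table")
    sub = persons.dropna(subset=[factor, "theta"])
    levels = sorted(sub[factor].unique())
    if len(levels) < 2:
        raise ValueError("group comparison needs at least 2 levels")
    samples = [sub.loc[sub[factor] == lv, "theta"].to_numpy() for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 persons")
    f_stat, p = stats.f_oneway(*samples)
    out = {
        "factor": factor,
        "levels": levels,
        "F": float(f_stat),
        "p": float(p),
        "df_between": len(levels) - 1,
        "df_within": int(len(sub) - len(levels)),
        "group_means": {lv: float(np.mean(s)) for lv, s in zip(levels, samples)},
    }
    if len(levels) == 2:
        out["t"] = float(np.sign(out["group_means"][levels[0]]
                                 - out["group_means"][levels[1]])
                         * np.sqrt(max(f_stat, 0.0)))
    return out


# ---------------------------------------------------------------------------
# report writing

def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(2)
    return out


def write_reports(
    data: ResponseMatrix,
    result: CalibrationResult,
    out_dir,
    dif_results: list[DIFResult] | None = None,
    kidmaps: list[KidmapRecord] | None = None,
    plots: bool = True,
) -> list[Path]:
    """Write items.tsv / persons.tsv (+ dif.tsv, kidmap JSON, SVG plots).

    TSV numbers are rounded to 2 decimals; the kidmap JSON keeps full
    precision for machine consumption.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "items.tsv"
    _fmt(result.items).to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out_dir / "persons.tsv"
    _fmt(result.persons).to_csv(p, sep="\t", index=False)
    written.append(p)

    if dif_results is not None:
        p = out_dir / "dif.tsv"
        _fmt(forest_table(dif_results)).to_csv(p, sep="\t", index=False)
        written.append(p)

    if kidmaps:
        payload = [
            {
                "person_id": k.person_id,
                "theta": k.theta,
                "se": k.se,
                "outfit_mnsq": k.outfit_mnsq,
                "items": k.rows.to_dict(orient="records"),
            }
            for k in kidmaps
        ]
        p = out_dir / "kidmap.json"
        p.write_text(json.dumps(payload, indent=1))
        written.append(p)

    if plots:
        written.extend(_render_plots(data, result, out_dir, dif_results, kidmaps))
    return written


def _render_plots(data, result, out_dir, dif_results, kidmaps) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []

    # item difficulty display with fit (DID-style)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    order = result.items.sort_values("difficulty")
    ax.errorbar(order["difficulty"], range(len(order)), xerr=order["se"], fmt="o")
    ax.set_yticks(range(len(order)), order["item_id"])
    ax.set_xlabel("difficulty (logits)")
    ax.set_title("Item difficulties with standard errors")
    p = out_dir / "did.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # Wright map
    wm = wright_map_data(result.persons, result.items)
    fig, (axp, axi) = plt.subplots(
        1, 2, figsize=(7, 4.5), sharey=True, width_ratios=[3, 1]
    )
    mids = (wm["bins"]["bin_low"] + wm["bins"]["bin_high"]) / 2
    axp.barh(mids, wm["bins"]["total"], height=0.45)
    axp.set_xlabel("persons")
    axp.set_ylabel("logits")
    axi.plot([0] * len(wm["items"]), wm["items"]["difficulty"], "s")
    for _, row in wm["items"].iterrows():
        axi.annotate(row["item_id"], (0.05, row["difficulty"]), fontsize=7)
    axi.set_xticks([])
    axi.set_xlim(-0.3, 1)
    fig.suptitle("Wright map: person distribution vs item locations")
    p = out_dir / "wright_map.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    if dif_results is not None:
        tab = forest_table(dif_results)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        y = range(len(tab))
        ax.hlines(y, tab["ci_low"], tab["ci_high"])
        ax.plot(tab["contrast"], y, "o")
        ax.axvline(0, ls="--", lw=0.8)
        ax.set_yticks(y, tab["item_id"])
        ax.set_xlabel("difficulty contrast (logits), 95% CI")
        ax.set_title("DIF forest plot")
        p = out_dir / "dif_forest.svg"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    for k in kidmaps or []:
        fig, ax = plt.subplots(figsize=(5, 4.5))
        correct = k.rows["observed"] == 1
        ax.plot(k.rows.loc[correct, "z"], k.rows.loc[correct, "difficulty"], "ko",
                label="correct")
        ax.plot(k.rows.loc[~correct, "z"], k.rows.loc[~correct, "difficulty"], "rx",
                label="incorrect")
        ax.axvline(2, ls="--", lw=0.8)
        ax.axvline(-2, ls="--", lw=0.8)
        ax.axhline(k.theta, color="gray", lw=0.8)
        ax.set_xlabel("standardized residual z")
        ax.set_ylabel("item difficulty (logits)")
        ax.set_title(f"KIDMAP {k.person_id} (theta={k.theta:.2f})")
        ax.legend(fontsize=7)
        p = out_dir / f"kidmap_{k.person_id}.svg"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
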