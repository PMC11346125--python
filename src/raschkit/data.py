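"""The persons x items dichotomous response container and its CSV format.

The on-disk format is a plain CSV with header ``person_id,group,item_*``;
cells are ``0``, ``1`` or ``NA`` (missing).  In memory the scores live in a
float array with NaN for missing, alongside person/item labels and an
optional per-person group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix"]


@dataclass
class ResponseMatrix:
    """Persons x items matrix of 0/1 scores with NaN for missing cells."""

    scores: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    groups: list[str] | None = None
    true_thetas: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D persons x items array")
        n, L = self.scores.shape
        if len(self.person_ids) != n or len(self.item_ids) != L:
            raise ValueError("label lengths do not match the score matrix")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("groups length does not match the number of persons")
        observed = self.scores[~np.isnan(self.scores)]
        if not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("scores must be 0, 1 or missing")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a response was observed."""
        return ~np.isnan(self.scores)

    def raw_person_scores(self) -> np.ndarray:
        return np.nansum(self.scores, axis=1)

    def raw_item_scores(self) -> np.ndarray:
        return np.nansum(self.scores, axis=0)

    def items_administered(self) -> np.ndarray:
        """Per-person count of non-missing responses."""
        return self.mask.sum(axis=1)

    def drop_persons(self, indices) -> "ResponseMatrix":
        keep = np.setdiff1d(np.arange(self.n_persons), np.asarray(indices, dtype=int))
        return ResponseMatrix(
            self.scores[keep],
            [self.person_ids[i] for i in keep],
            list(self.item_ids),
            None if self.groups is None else [self.groups[i] for i in keep],
            None if self.true_thetas is None else self.true_thetas[keep],
        )

    def drop_items(self, indices) -> "ResponseMatrix":
        keep = np.setdiff1d(np.arange(self.n_items), np.asarray(indices, dtype=int))
        return ResponseMatrix(
            self.scores[:, keep],
            list(self.person_ids),
            [self.item_ids[i] for i in keep],
            self.groups,
            self.true_thetas,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.item_ids)
        df.insert(0, "group", self.groups if self.groups is not None else "")
        df.insert(0, "person_id", self.person_ids)
        return df

    def to_csv(self, path) -> None:
        df = self.to_frame()
        for c in self.item_ids:
            df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        """Read and validate a response CSV; errors name the offending cell."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "person_id" not in df.columns:
            raise ValueError(f"{path}: missing required 'person_id' column")
        item_cols = [c for c in df.columns if c not in ("person_id", "group")]
        if not item_cols:
            raise ValueError(f"{path}: no item columns found")
        scores = np.full((len(df), len(item_cols)), np.nan)
        for j, col in enumerate(item_cols):
            for i, raw in enumerate(df[col]):
                cell = raw.strip()
                if cell in ("NA", "", "nan"):
                    continue
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"{path}: invalid cell {raw!r} at row {i + 2}, "
                        f"column {col!r} (expected 0, 1 or NA)"
                    )
                scores[i, j] = float(cell)
        groups = list(df["group"]) if "group" in df.columns else None
        if groups is not None and all(g == "" for g in groups):
            groups = None
        return cls(scores, list(df["person_id"]), item_cols, groups)
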