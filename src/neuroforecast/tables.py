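"""Behavioral and outcome tables accompanying the EEG study.

Four CSV-shaped tables keyed on ``video_id``:

* ``ratings`` — one row per subject x video with the five 7-point investment
  interest items (q1..q5), the binary deal prediction, the fourteen dynamic
  capability items (dc1..dc14) and demographics;
* ``population`` — per-video mean investment interest from a large online
  rater pool;
* ``outcomes`` — per-video real-world deal outcome (0/1) and funding amount
  in USD;
* ``sentiment`` — optional per-video transcript sentiment covariates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTEREST_ITEMS = [f"q{i}" for i in range(1, 6)]
DC_ITEMS = [f"dc{i}" for i in range(1, 15)]


class TableValidationError(ValueError):
    """Raised when a study table violates its schema or cross-table contract."""


@dataclass
class StudyTables:
    """Validated bundle of behavioral, population, and outcome tables."""

    ratings: pd.DataFrame
    population: pd.DataFrame
    outcomes: pd.DataFrame
    sentiment: pd.DataFrame | None = None
    videos: pd.DataFrame | None = None  # optional video_id, duration_s

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        req = ["subject_id", "video_id", *INTEREST_ITEMS, "deal_prediction"]
        missing = [c for c in req if c not in self.ratings.columns]
        if missing:
            raise TableValidationError(f"ratings table missing columns: {missing}")
        item_cols = [c for c in INTEREST_ITEMS + DC_ITEMS if c in self.ratings.columns]
        items = self.ratings[item_cols]
        bad = items.notna() & ((items < 1) | (items > 7))
        if bad.to_numpy().any():
            row, col = np.argwhere(bad.to_numpy())[0]
            raise TableValidationError(
                f"Likert item out of [1, 7]: column {item_cols[col]!r}, "
                f"row {bad.index[row]} (subject "
                f"{self.ratings['subject_id'].iloc[row]!r}, video "
                f"{self.ratings['video_id'].iloc[row]!r})"
            )
        if not set(self.ratings["deal_prediction"].dropna().unique()) <= {0, 1}:
            raise TableValidationError("deal_prediction must be binary 0/1")

        for name, df, cols in [
            ("population", self.population, ["video_id", "pop_interest"]),
            ("outcomes", self.outcomes, ["video_id", "deal", "amount"]),
        ]:
            miss = [c for c in cols if c not in df.columns]
            if miss:
                raise TableValidationError(f"{name} table missing columns: {miss}")

        if not set(self.outcomes["deal"].unique()) <= {0, 1}:
            raise TableValidationError("outcomes.deal must be binary 0/1")
        if (self.outcomes["amount"] < 0).any():
            raise TableValidationError("outcomes.amount must be non-negative")
        odd = self.outcomes[(self.outcomes["deal"] == 1) & (self.outcomes["amount"] <= 0)]
        if len(odd):
            warnings.warn(
                f"outcomes table has deal=1 with amount=0 for videos "
                f"{sorted(odd['video_id'])}", stacklevel=2,
            )
        zero_amt = self.outcomes[(self.outcomes["deal"] == 0) & (self.outcomes["amount"] > 0)]
        if len(zero_amt):
            raise TableValidationError(
                f"unfunded videos with positive amount: {sorted(zero_amt['video_id'])}"
            )

        ids = set(self.outcomes["video_id"])
        for name, df in [("ratings", self.ratings), ("population", self.population)] + (
            [("sentiment", self.sentiment)] if self.sentiment is not None else []
        ):
            other = set(df["video_id"])
            if other != ids:
                raise TableValidationError(
                    f"video_id mismatch between outcomes and {name}: "
                    f"missing {sorted(ids - other)}, extra {sorted(other - ids)}"
                )

    @property
    def video_ids(self) -> list[str]:
        return sorted(self.outcomes["video_id"])

    @property
    def n_videos(self) -> int:
        return len(self.outcomes)

    def interest_composite(self) -> pd.DataFrame:
        """Per subject x video mean of the five interest items."""
        out = self.ratings[["subject_id", "video_id"]].copy()
        out["interest"] = self.ratings[INTEREST_ITEMS].mean(axis=1)
        return out

    def dc_composite(self) -> pd.DataFrame:
        """Per-subject mean of the fourteen dynamic-capability items."""
        cols = [c for c in DC_ITEMS if c in self.ratings.columns]
        if not cols:
            raise TableValidationError("ratings table has no dc1..dc14 columns")
        df = self.ratings.groupby("subject_id")[cols].first()
        return df.mean(axis=1).rename("dc").reset_index()

    def video_table(self) -> pd.DataFrame:
        """Per-video join of population interest, outcomes, and sentiment."""
        df = self.outcomes.merge(self.population, on="video_id")
        if self.sentiment is not None:
            df = df.merge(self.sentiment, on="video_id")
        return df.sort_values("video_id").reset_index(drop=True)
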