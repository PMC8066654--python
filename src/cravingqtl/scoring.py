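"""Scoring of the 14-item heroin-use and craving (HUC) questionnaire.

Each item is scored 0-4. Part I (items 1-6, range 0-24) measures the urge
for heroin; Part II (items 7-14, range 0-32) measures frequency of use,
daily-life disturbance, anxiety and the ability to overcome heroin use.
Higher scores mean more severe craving. The three analysed phenotypes are
the Part I sum ("urge"), the Part II sum ("ability") and their total.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

N_ITEMS = 14
ITEM_MAX = 4
PART1_ITEMS = tuple(range(1, 7))     # HUC 1-6
PART2_ITEMS = tuple(range(7, 15))    # HUC 7-14
ITEM_COLUMNS = tuple(f"huc{i:02d}" for i in range(1, N_ITEMS + 1))
PART1_COLUMNS = ITEM_COLUMNS[:6]
PART2_COLUMNS = ITEM_COLUMNS[6:]
URGE_MAX = len(PART1_ITEMS) * ITEM_MAX       # 24
ABILITY_MAX = len(PART2_ITEMS) * ITEM_MAX    # 32
TOTAL_MAX = URGE_MAX + ABILITY_MAX           # 56

PHENOTYPES = ("total", "urge", "ability")


class HUCScores(NamedTuple):
    urge: int
    ability: int
    total: int


def score_huc(items: Sequence[int]) -> HUCScores:
    """Score one questionnaire response into (urge, ability, total)."""
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item scores, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"item huc{i:02d} is missing")
        if int(v) != v or not 0 <= int(v) <= ITEM_MAX:
            raise ValueError(f"item huc{i:02d}={v!r} outside 0..{ITEM_MAX}")
    ivals = [int(v) for v in items]
    urge = sum(ivals[:6])
    ability = sum(ivals[6:])
    return HUCScores(urge=urge, ability=ability, total=urge + ability)


def score_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Add urge/ability/total columns to a phenotype table.

    Records with any missing or out-of-range item get NaN scores (no
    imputation); the caller decides whether to drop them. Returns a copy.
    """
    out = phenotypes.copy()
    items = out.reindex(columns=list(ITEM_COLUMNS))
    vals = items.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok = (np.isfinite(vals) & (vals >= 0) & (vals <= ITEM_MAX)
              & (vals == np.round(vals))).all(axis=1)
    urge = vals[:, :6].sum(axis=1)
    ability = vals[:, 6:].sum(axis=1)
    out["urge"] = np.where(ok, urge, np.nan)
    out["ability"] = np.where(ok, ability, np.nan)
    out["total"] = np.where(ok, urge + ability, np.nan)
    return out


class HUCScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping item columns huc01..huc14 to subscale scores.

    ``fit`` records how many records were unscorable (missing items);
    ``transform`` returns the table with urge/ability/total appended.

    Attributes
    ----------
    n_records_ : int
        Number of records seen at fit.
    n_unscorable_ : int
        Records with at least one missing/out-of-range item.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "HUCScorer":
        missing = [c for c in ITEM_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"missing item column(s): {missing}")
        scored = score_table(X)
        self.n_records_ = len(X)
        self.n_unscorable_ = int(scored["total"].isna().sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return score_table(X)


def summarize_scores(scores: pd.DataFrame,
                     groups: Sequence | None = None) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1) of urge, ability and total.

    Parameters
    ----------
    scores : DataFrame with urge/ability/total columns (NaN rows ignored).
    groups : optional per-row labels; omitted = one overall group ("all").

    Returns a DataFrame indexed by group with columns n and
    {urge,ability,total}_{mean,sd}. SD is NaN for groups with n < 2.
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    df = scores[list(PHENOTYPES)].copy()
    df["_group"] = "all" if groups is None else list(groups)
    df = df.dropna(subset=list(PHENOTYPES))
    rows = {}
    for label, sub in df.groupby("_group", sort=True):
        row = {"n": len(sub)}
        for ph in PHENOTYPES:
            row[f"{ph}_mean"] = sub[ph].mean()
            row[f"{ph}_sd"] = sub[ph].std(ddof=1) if len(sub) >= 2 else np.nan
        rows[label] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
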