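"""Supermarket flyer promotion indicators.

One record per promoted product.  Indicators are computed over all
records of a supermarket and again restricted to flyer covers, since
cover promotions are reported separately from inside pages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PromotionError",
    "promotion_indicators",
    "promotion_table",
    "category_shares",
    "top_categories",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "supermarket_id",
    "week",
    "placement",
    "who_category",
    "nova_group",
    "nutriscore_class",
    "has_promotional_character",
    "has_premium_offer",
    "is_fresh_fruit_veg",
)

PLACEMENTS = ("cover", "inside")


class PromotionError(ValueError):
    pass


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise PromotionError(f"flyer records: missing column(s) {sorted(missing)}")
    bad = set(records["placement"].unique()) - set(PLACEMENTS)
    if bad:
        raise PromotionError(f"flyer records: unknown placement value {sorted(bad)[0]!r}")
    return records


def _indicator_row(sub: pd.DataFrame, supermarket_id: str, scope: str) -> dict:
    n = len(sub)
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / n
    shown = sub["nutriscore_class"].fillna("").astype(str).str.strip() != ""
    return dict(
        supermarket_id=supermarket_id,
        scope=scope,
        n_promotions=n,
        pct_upf=pct(sub["nova_group"].astype(int) == 4),
        pct_fresh_fruit_veg=pct(sub["is_fresh_fruit_veg"].astype(bool)),
        pct_character=pct(sub["has_promotional_character"].astype(bool)),
        pct_premium=pct(sub["has_premium_offer"].astype(bool)),
        pct_nutriscore_shown=pct(shown),
    )


def promotion_indicators(records: pd.DataFrame, supermarket_id: str) -> pd.DataFrame:
    """Indicator rows for one supermarket: scope ``all`` and ``cover``.

    Refuses an empty record set.  The cover scope is omitted when the
    supermarket ran no cover promotions.
    """
    records = _validate(records)
    sub = records[records["supermarket_id"] == supermarket_id]
    if sub.empty:
        raise PromotionError(f"no promotion records for supermarket '{supermarket_id}'")
    rows = [_indicator_row(sub, supermarket_id, "all")]
    cover = sub[sub["placement"] == "cover"]
    if not cover.empty:
        rows.append(_indicator_row(cover, supermarket_id, "cover"))
    return pd.DataFrame(rows)


def promotion_table(records: pd.DataFrame) -> pd.DataFrame:
    """Indicator rows for every supermarket present in the records."""
    records = _validate(records)
    frames = [
        promotion_indicators(records, sid)
        for sid in sorted(records["supermarket_id"].astype(str).unique())
    ]
    return pd.concat(frames, ignore_index=True)


def category_shares(records: pd.DataFrame) -> pd.Series:
    """Percentage of promotions per WHO category (sums to 100)."""
    records = _validate(records)
    if records.empty:
        raise PromotionError("empty record set")
    counts = records["who_category"].value_counts()
    return (100.0 * counts / counts.sum()).rename("share_pct")


def top_categories(records: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k promoted WHO categories; ties broken by category name."""
    if k < 1:
        raise PromotionError("k must be >= 1")
    shares = category_shares(records)
    if k > len(shares):
        warnings.warn(
            f"k={k} exceeds the {len(shares)} observed categories; truncating", stacklevel=2
        )
        k = len(shares)
    df = shares.rename_axis("who_category").reset_index()
    df = df.sort_values(["share_pct", "who_category"], ascending=[False, True], kind="mergesort")
    return df.head(k).reset_index(drop=True)
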