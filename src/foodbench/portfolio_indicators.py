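"""Per-company performance indicators from profiled portfolios."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PortfolioSummary",
    "PortfolioError",
    "PortfolioTooSmall",
    "summarize_portfolio",
    "summarize_portfolios",
    "aggregate_industry",
    "CLASS_CODES",
    "MIN_PORTFOLIO_SIZE",
]

CLASS_CODES = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}

#: companies with fewer products are flagged instead of summarised
MIN_PORTFOLIO_SIZE = 3

INDICATOR_COLUMNS = (
    "pct_AB",
    "pct_DE",
    "pct_upf",
    "pct_not_permitted",
    "pct_displaying_label",
    "median_class_code",
)


class PortfolioError(ValueError):
    pass


class PortfolioTooSmall(PortfolioError):
    """Portfolio below the reporting threshold: flagged, not summarised."""


@dataclass(frozen=True)
class PortfolioSummary:
    company_id: str
    n_products: int
    median_class: str
    median_class_code: int
    median_score: float  # median of the numeric Nutri-Score points balance
    pct_AB: float
    pct_C: float
    pct_DE: float
    pct_upf: float
    pct_not_permitted: float
    pct_displaying_label: float


def _median_class_code(codes: np.ndarray) -> int:
    """Ordinal median; an even-n midpoint rounds toward the less healthy class."""
    m = float(np.median(codes))
    return int(math.ceil(m - 1e-9))


def summarize_portfolio(
    profiled: pd.DataFrame,
    company_id: Optional[str] = None,
    min_size: int = 1,
) -> PortfolioSummary:
    """Summarise the profiled products of one company.

    ``profiled`` is the per-product output of
    :func:`foodbench.nutrient_profiling.profile_products` restricted to
    one company.  Raises :class:`PortfolioTooSmall` below ``min_size``
    and :class:`PortfolioError` on an empty portfolio.
    """
    if len(profiled) == 0:
        raise PortfolioError("empty portfolio")
    if company_id is None:
        ids = profiled["company_id"].unique()
        if len(ids) != 1:
            raise PortfolioError(f"portfolio spans multiple companies: {sorted(map(str, ids))}")
        company_id = str(ids[0])
    n = len(profiled)
    if n < min_size:
        raise PortfolioTooSmall(f"company '{company_id}': {n} product(s) < minimum {min_size}")
    codes = profiled["nutri_class"].map(CLASS_CODES)
    if codes.isna().any():
        raise PortfolioError(f"company '{company_id}': invalid Nutri-Score class value")
    codes = codes.to_numpy(int)
    med_code = _median_class_code(codes)
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / n
    return PortfolioSummary(
        company_id=company_id,
        n_products=n,
        median_class=CODE_CLASSES[med_code],
        median_class_code=med_code,
        median_score=float(np.median(profiled["final_score"].to_numpy(float))),
        pct_AB=pct(codes <= 2),
        pct_C=pct(codes == 3),
        pct_DE=pct(codes >= 4),
        pct_upf=pct(profiled["nova_group"].to_numpy(int) == 4),
        pct_not_permitted=pct(~profiled["permitted"].to_numpy(bool)),
        pct_displaying_label=pct(profiled["displays_nutriscore"].to_numpy(bool)),
    )


def summarize_portfolios(
    profiled: pd.DataFrame,
    companies: Optional[pd.DataFrame] = None,
    min_size: int = MIN_PORTFOLIO_SIZE,
) -> tuple[pd.DataFrame, list[str]]:
    """Summarise every company; return (summaries, flagged company ids).

    Companies with fewer than ``min_size`` products are flagged and
    excluded from the summaries frame.  ``companies`` may supply an
    ``industry`` column to merge in.
    """
    rows, flagged = [], []
    for cid, sub in profiled.groupby("company_id", sort=True):
        try:
            rows.append(summarize_portfolio(sub, company_id=str(cid), min_size=min_size).__dict__)
        except PortfolioTooSmall:
            flagged.append(str(cid))
    out = pd.DataFrame(rows)
    if companies is not None and not out.empty:
        out = out.merge(
            companies[["company_id", "industry"]].drop_duplicates(), on="company_id", how="left"
        )
    return out, flagged


def aggregate_industry(summaries: pd.DataFrame, industry: str) -> pd.DataFrame:
    """Median / min / max per indicator across one industry's companies."""
    if "industry" not in summaries.columns:
        raise PortfolioError("summaries frame lacks an 'industry' column")
    known = set(summaries["industry"].unique())
    if industry not in known:
        raise PortfolioError(f"unknown industry '{industry}'")
    sub = summaries[summaries["industry"] == industry]
    rows = []
    for col in INDICATOR_COLUMNS:
        vals = sub[col].to_numpy(float)
        rows.append(
            dict(
                industry=industry,
                indicator=col,
                n_companies=len(sub),
                median=float(np.median(vals)),
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return pd.DataFrame(rows)
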