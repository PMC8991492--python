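"""Commitment-practice correlation tests.

Spearman rank correlation on mid-ranks, with an exact permutation
p-value for n <= 8 and the t approximation otherwise (the method is
reported in every result).  :func:`linkage_suite` runs the fixed set of
domain-indicator pairings: the product-formulation domain score against
portfolio %A/B, %D/E, median class (numeric 1-5) and %ultra-processed,
and the promotion domain score against %not-permitted.

Interpretation conventions carried on each result: ``strong`` when
|rho| > 0.5, ``significant`` when p < 0.05.  A Holm-adjusted p column is
emitted alongside as a clearly-marked extension; no correction is
applied to the primary p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ConstantInputError",
    "LinkageError",
    "spearman",
    "spearman_rho_p",
    "linkage_suite",
    "PAIRINGS",
]

STRONG_RHO = 0.5
ALPHA = 0.05

#: (domain, indicator column, expected sign under positive coupling)
PAIRINGS = (
    ("product_formulation", "pct_AB", +1),
    ("product_formulation", "pct_DE", -1),
    ("product_formulation", "median_class_code", -1),
    ("product_formulation", "pct_upf", -1),
    ("promotion", "pct_not_permitted", -1),
)


class LinkageError(ValueError):
    pass


class ConstantInputError(LinkageError):
    """Rho is undefined when either variable is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    domain: str
    indicator: str
    n: int
    rho: float
    p_value: float
    method: str
    note: str = ""

    @property
    def strong(self) -> bool:
        return bool(np.isfinite(self.rho) and abs(self.rho) > STRONG_RHO)

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA)


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _centred_ranks(values: np.ndarray) -> np.ndarray:
    r = stats.rankdata(values)
    return r - r.mean()


def spearman_rho_p(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_max_n: int = 8,
) -> tuple[float, float, str]:
    """Spearman rho (Pearson on mid-ranks) and two-sided p-value.

    ``method``: "auto" (exact for n <= ``exact_max_n``), "exact" or
    "t_approx".  Exact enumeration counts permutations with
    |rho_perm| >= |rho_observed|.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise LinkageError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise LinkageError("need at least 3 observations")
    rx, ry = _centred_ranks(x), _centred_ranks(y)
    sx = np.sqrt((rx**2).sum())
    sy = np.sqrt((ry**2).sum())
    if sx == 0 or sy == 0:
        raise ConstantInputError("constant input: rho undefined")
    rho = float((rx * ry).sum() / (sx * sy))

    if method == "auto":
        method = "exact" if n <= exact_max_n else "t_approx"
    if method == "exact":
        if n > exact_max_n:
            raise LinkageError(f"exact enumeration limited to n <= {exact_max_n}")
        perms = _permutation_matrix(n)
        rho_perm = (ry[perms] * rx).sum(axis=1) / (sx * sy)
        p = float((np.abs(rho_perm) >= abs(rho) - 1e-12).mean())
        return rho, p, "exact"
    if method == "t_approx":
        if abs(rho) >= 1.0 - 1e-15:
            return rho, 0.0, "t_approx"
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        return rho, min(1.0, p), "t_approx"
    raise LinkageError(f"unknown method '{method}'")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    domain: str = "",
    indicator: str = "",
    method: str = "auto",
) -> CorrelationResult:
    """Correlation result for one domain-indicator pairing.

    Raises :class:`ConstantInputError` when either input is constant
    (mirrors portfolios of companies that made no commitments at all).
    """
    rho, p, used = spearman_rho_p(x, y, method=method)
    return CorrelationResult(
        domain=domain, indicator=indicator, n=len(np.asarray(x)), rho=rho, p_value=p, method=used
    )


def _holm(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, NaN-safe."""
    p = np.asarray(p_values, float)
    adjusted = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    adjusted[mask] = adj
    return adjusted


def linkage_suite(
    bia_scores: pd.DataFrame,
    summaries: pd.DataFrame,
    method: str = "auto",
) -> pd.DataFrame:
    """Run every commitment-practice pairing on companies present in both inputs.

    ``bia_scores`` must carry ``company_id`` plus the domain-score
    columns; ``summaries`` must carry ``company_id`` plus the indicator
    columns.  Companies missing from either side are excluded pairwise;
    exclusion counts are recorded in the ``note`` column.  Constant
    inputs yield a row with ``rho`` NaN rather than a silent drop.
    """
    for colset, frame, name in (
        ({"company_id"}, bia_scores, "bia_scores"),
        ({"company_id"}, summaries, "summaries"),
    ):
        if not colset <= set(frame.columns):
            raise LinkageError(f"{name}: missing company_id column")
    merged = bia_scores.merge(summaries, on="company_id", how="inner", suffixes=("", "_ind"))
    if merged.empty:
        raise LinkageError("join of scores and summaries is empty")

    rows = []
    for domain, indicator, expected_sign in PAIRINGS:
        if domain not in merged.columns:
            raise LinkageError(f"bia_scores: missing domain column '{domain}'")
        if indicator not in merged.columns:
            raise LinkageError(f"summaries: missing indicator column '{indicator}'")
        sub = merged[[domain, indicator]].dropna()
        n_excluded = len(merged) - len(sub)
        note = f"excluded={n_excluded}" if n_excluded else ""
        if len(sub) < 3:
            rows.append(
                dict(domain=domain, indicator=indicator, n=len(sub), rho=np.nan,
                     p_value=np.nan, method="", strong=False, significant=False,
                     expected_sign=expected_sign, note=(note + ";too_few").strip(";"))
            )
            continue
        try:
            res = spearman(sub[domain], sub[indicator], domain, indicator, method=method)
            rows.append(
                dict(domain=domain, indicator=indicator, n=res.n, rho=res.rho,
                     p_value=res.p_value, method=res.method, strong=res.strong,
                     significant=res.significant, expected_sign=expected_sign, note=note)
            )
        except ConstantInputError:
            rows.append(
                dict(domain=domain, indicator=indicator, n=len(sub), rho=np.nan,
                     p_value=np.nan, method="", strong=False, significant=False,
                     expected_sign=expected_sign, note=(note + ";constant_input").strip(";"))
            )
    out = pd.DataFrame(rows)
    out["p_holm_extension"] = _holm(out["p_value"].to_numpy())
    return out
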