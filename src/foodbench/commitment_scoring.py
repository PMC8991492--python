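"""Commitment-score aggregation and engagement comparisons.

Indicator-level scores are aggregated into per-domain percentages
(sum of raw over sum of max, inapplicable indicators excluded) and a
weighted overall percentage.  Engagement is tested with a one-sided
Wilcoxon signed-rank test (scores after verification vs. before) and a
two-sided Wilcoxon rank-sum test (participants vs. non-participants).

Both rank tests carry their own exact null distributions, computed by
convolution over sign assignments (signed rank) or label assignments
(rank sum) on mid-ranks, so that small samples -- including tied ranks,
which rule out the textbook tables -- get exact p-values.  Larger
samples fall back to the tie-corrected normal approximation; the method
used is always reported in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DOMAINS",
    "INDUSTRIES",
    "IndicatorScore",
    "CommitmentSheet",
    "WeightTable",
    "UndefinedDomainError",
    "ScoringError",
    "domain_score",
    "overall_score",
    "score_frame",
    "sheets_from_frame",
    "engagement_effect",
    "participation_gap",
    "signed_rank_test",
    "rank_sum_test",
    "RankTestResult",
]

DOMAINS = (
    "corporate_strategy",
    "product_formulation",
    "nutrition_labelling",
    "promotion",
    "accessibility",
    "relationships",
)

INDUSTRIES = ("manufacturer", "supermarket", "quick_service")

STAGES = ("public_only", "verified")


class ScoringError(ValueError):
    """Invalid commitment-scoring input."""


class UndefinedDomainError(ScoringError):
    """Every indicator of the domain is inapplicable: score undefined, not 0."""


@dataclass(frozen=True)
class IndicatorScore:
    indicator_id: str
    domain: str
    raw: float
    max: float
    applicable: bool = True

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ScoringError(f"unknown domain '{self.domain}'")
        if self.max <= 0:
            raise ScoringError(f"indicator '{self.indicator_id}': max must be positive")
        if self.applicable and not 0 <= self.raw <= self.max:
            raise ScoringError(
                f"indicator '{self.indicator_id}': raw {self.raw} outside [0, {self.max}]"
            )


@dataclass(frozen=True)
class CommitmentSheet:
    """All indicator scores of one company at one assessment stage."""

    company_id: str
    industry: str
    stage: str
    indicators: tuple[IndicatorScore, ...]

    def __post_init__(self):
        if self.industry not in INDUSTRIES:
            raise ScoringError(f"unknown industry '{self.industry}'")
        if self.stage not in STAGES:
            raise ScoringError(f"unknown stage '{self.stage}'")
        present = {i.domain for i in self.indicators}
        missing = [d for d in DOMAINS if d not in present]
        if missing:
            raise ScoringError(
                f"company '{self.company_id}': no indicators for domain(s) {missing}"
            )


def sheets_from_frame(df: pd.DataFrame) -> list[CommitmentSheet]:
    """Build sheets from the long ``commitments.csv`` layout."""
    required = {"company_id", "industry", "stage", "domain", "indicator_id", "raw", "max", "applicable"}
    missing = required - set(df.columns)
    if missing:
        raise ScoringError(f"commitments frame: missing column(s) {sorted(missing)}")
    sheets = []
    for (cid, stage), sub in df.groupby(["company_id", "stage"], sort=True):
        industries = sub["industry"].unique()
        if len(industries) != 1:
            raise ScoringError(f"company '{cid}': inconsistent industry labels")
        indicators = tuple(
            IndicatorScore(
                indicator_id=str(r.indicator_id),
                domain=str(r.domain),
                raw=float(r.raw),
                max=float(r.max),
                applicable=bool(r.applicable),
            )
            for r in sub.itertuples()
        )
        sheets.append(CommitmentSheet(str(cid), str(industries[0]), str(stage), indicators))
    return sheets


def domain_score(sheet: CommitmentSheet, domain: str) -> float:
    """100 x sum(raw) / sum(max) over applicable indicators of the domain."""
    if domain not in DOMAINS:
        raise ScoringError(f"unknown domain '{domain}'")
    applicable = [i for i in sheet.indicators if i.domain == domain and i.applicable]
    if not applicable:
        raise UndefinedDomainError(
            f"company '{sheet.company_id}': all '{domain}' indicators inapplicable"
        )
    return 100.0 * sum(i.raw for i in applicable) / sum(i.max for i in applicable)


class WeightTable:
    """Per-industry domain weights, summing to 1 per industry."""

    def __init__(self, weights: dict[str, dict[str, float]]):
        for industry, w in weights.items():
            if industry not in INDUSTRIES:
                raise ScoringError(f"unknown industry '{industry}' in weight table")
            unknown = set(w) - set(DOMAINS)
            if unknown:
                raise ScoringError(f"unknown domain(s) {sorted(unknown)} in weight table")
            if any(v < 0 for v in w.values()):
                raise ScoringError(f"negative weight for industry '{industry}'")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ScoringError(f"weights for industry '{industry}' do not sum to 1")
        self.weights = {ind: dict(w) for ind, w in weights.items()}

    def __getitem__(self, industry: str) -> dict[str, float]:
        if industry not in self.weights:
            raise ScoringError(f"no weights defined for industry '{industry}'")
        return self.weights[industry]

    @classmethod
    def uniform(cls) -> "WeightTable":
        w = {d: 1.0 / len(DOMAINS) for d in DOMAINS}
        return cls({ind: dict(w) for ind in INDUSTRIES})

    @classmethod
    def from_yaml(cls, path) -> "WeightTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh)["weights"])

    @classmethod
    def default(cls) -> "WeightTable":
        """Illustrative default shipped with the package (uniform weights)."""
        text = resources.files("foodbench").joinpath("data/weights.yaml").read_text()
        return cls(yaml.safe_load(text)["weights"])


def overall_score(sheet: CommitmentSheet, weights: WeightTable) -> float:
    """Weighted mean of domain scores.

    Domains whose score is undefined (all indicators inapplicable) are
    dropped and the remaining weights renormalised.
    """
    w = weights[sheet.industry]
    scores, used = {}, {}
    for d in DOMAINS:
        try:
            scores[d] = domain_score(sheet, d)
            used[d] = w.get(d, 0.0)
        except UndefinedDomainError:
            continue
    total = sum(used.values())
    if total <= 1e-12:
        raise ScoringError(
            f"company '{sheet.company_id}': no weight left after dropping undefined domains"
        )
    return sum(used[d] / total * scores[d] for d in used)


def score_frame(commitments: pd.DataFrame, weights: WeightTable | None = None) -> pd.DataFrame:
    """Aggregate a long commitments frame into ``bia_scores`` rows.

    One row per company x stage: the six domain scores (NaN when
    undefined) and the weighted overall score.
    """
    weights = weights or WeightTable.uniform()
    rows = []
    for sheet in sheets_from_frame(commitments):
        row = {"company_id": sheet.company_id, "industry": sheet.industry, "stage": sheet.stage}
        for d in DOMAINS:
            try:
                row[d] = domain_score(sheet, d)
            except UndefinedDomainError:
                row[d] = np.nan
        row["overall"] = overall_score(sheet, weights)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["industry", "company_id", "stage"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "exact" or "normal_approx"
    alternative: str
    extra: dict = field(default_factory=dict)


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks scaled by 2 so ties (.5 steps) become exact integers."""
    ranks = stats.rankdata(values)
    doubled = np.rint(2.0 * ranks).astype(int)
    return doubled


def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of sign assignments by doubled positive-rank sum W+."""
    total = int(ranks2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in ranks2:
        nxt = poly.copy()
        nxt[r:] += poly[: total + 1 - r]
        poly = nxt
    return poly


def signed_rank_test(
    diffs: Sequence[float],
    alternative: str = "greater",
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
) -> RankTestResult:
    """Wilcoxon signed-rank test on a vector of paired differences.

    ``zero_method='wilcox'`` drops zero differences before ranking (the
    classic convention); ``'pratt'`` ranks with zeros included and drops
    them afterwards.  Exact p-values (valid under ties) are used up to
    ``exact_max_n`` non-zero differences.
    """
    d = np.asarray(diffs, float)
    if zero_method not in ("wilcox", "pratt"):
        raise ScoringError(f"unknown zero_method '{zero_method}'")
    if alternative not in ("greater", "less", "two-sided"):
        raise ScoringError(f"unknown alternative '{alternative}'")
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    if nonzero.sum() < 2:
        raise ScoringError("fewer than 2 non-zero differences: signed-rank test refused")
    if zero_method == "wilcox":
        d = d[nonzero]
        ranks2 = _doubled_midranks(np.abs(d))
    else:
        ranks2 = _doubled_midranks(np.abs(d))[nonzero]
        d = d[nonzero]
    n = len(d)
    w2 = int(ranks2[d > 0].sum())

    if n <= exact_max_n:
        counts = _signed_rank_counts(ranks2)
        denom = 2.0**n
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        # Normal approximation; using actual mid-ranks in the variance
        # sum is the tie correction.
        mean = ranks2.sum() / 4.0
        var = (ranks2.astype(float) ** 2).sum() / 16.0
        z_num = w2 / 2.0 - mean
        sd = math.sqrt(var)
        if sd == 0:
            raise ScoringError("zero variance in signed-rank approximation")
        if alternative == "greater":
            p = stats.norm.sf((z_num - 0.5) / sd)
        elif alternative == "less":
            p = stats.norm.cdf((z_num + 0.5) / sd)
        else:
            p = min(1.0, 2.0 * stats.norm.sf((abs(z_num) - 0.5) / sd))
        method = "normal_approx"
    return RankTestResult(
        statistic=w2 / 2.0,
        p_value=float(p),
        n=n,
        method=method,
        alternative=alternative,
        extra={"n_zero_dropped": n_zero, "zero_method": zero_method},
    )


def _rank_sum_counts(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Counts of size-``n1`` label assignments by doubled rank sum."""
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n1]


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 20,
) -> RankTestResult:
    """Wilcoxon rank-sum test, exact for combined n <= ``exact_max_n``.

    The exact two-sided p doubles the smaller tail of the enumeration
    distribution (capped at 1).  Larger samples use the tie-corrected
    normal approximation via Mann-Whitney U.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ScoringError("rank-sum test refused: one group is empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ScoringError(f"unknown alternative '{alternative}'")
    n1, n = len(x), len(x) + len(y)
    combined = np.concatenate([x, y])
    ranks2 = _doubled_midranks(combined)
    w2 = int(ranks2[:n1].sum())

    if n <= exact_max_n:
        counts = _rank_sum_counts(ranks2, n1)
        denom = counts.sum()  # == C(n, n1)
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approx"
    return RankTestResult(
        statistic=w2 / 2.0,
        p_value=float(p),
        n=n,
        method=method,
        alternative=alternative,
        extra={"n1": n1, "n2": len(y)},
    )


def engagement_effect(
    pre: Sequence[float] | pd.Series,
    post: Sequence[float] | pd.Series,
    zero_method: str = "wilcox",
) -> RankTestResult:
    """One-sided (post > pre) signed-rank test on paired company scores."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if len(pre) != len(post):
        raise ScoringError("pre and post score vectors differ in length")
    result = signed_rank_test(post - pre, alternative="greater", zero_method=zero_method)
    extra = dict(result.extra)
    extra.update(median_pre=float(np.median(pre)), median_post=float(np.median(post)))
    return RankTestResult(
        statistic=result.statistic,
        p_value=result.p_value,
        n=result.n,
        method=result.method,
        alternative=result.alternative,
        extra=extra,
    )


def participation_gap(
    participant_scores: Sequence[float],
    nonparticipant_scores: Sequence[float],
) -> RankTestResult:
    """Two-sided rank-sum test comparing participants with non-participants."""
    return rank_sum_test(participant_scores, nonparticipant_scores, alternative="two-sided")
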