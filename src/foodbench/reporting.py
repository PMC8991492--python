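"""Benchmark report: per-industry rankings with tertile bands."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["tertile_bands", "render_report", "ReportError"]

#: indicator -> True when larger values are better
INDICATOR_DIRECTION = {
    "overall": True,
    "pct_AB": True,
    "pct_displaying_label": True,
    "pct_DE": False,
    "pct_upf": False,
    "pct_not_permitted": False,
    "median_class_code": False,
}


class ReportError(ValueError):
    pass


def tertile_bands(values: pd.Series, higher_better: bool = True) -> pd.Series:
    """Rank-based thirds (ceil split); ties broken by the index label.

    Returns "top" / "middle" / "bottom" per entry, or "na" throughout
    when fewer than 3 entries are available.
    """
    n = len(values)
    if n < 3:
        return pd.Series("na", index=values.index)
    order = sorted(
        values.index,
        key=lambda i: ((-values[i] if higher_better else values[i]), str(i)),
    )
    t = math.ceil(n / 3)
    bands = {}
    for pos, idx in enumerate(order):
        if pos < t:
            bands[idx] = "top"
        elif pos >= n - t:
            bands[idx] = "bottom"
        else:
            bands[idx] = "middle"
    return pd.Series(bands).reindex(values.index)


def render_report(
    bia_scores: pd.DataFrame,
    summaries: pd.DataFrame,
    stage: str = "verified",
) -> tuple[pd.DataFrame, str]:
    """Companies sorted per industry by descending overall score, each
    indicator annotated with its within-industry tertile band.

    Returns the report frame and a plain-text summary.  Industries with
    fewer than 3 companies skip banding (noted in the text).
    """
    scores = bia_scores[bia_scores["stage"] == stage] if "stage" in bia_scores else bia_scores
    if scores.empty:
        raise ReportError(f"no scores for stage '{stage}'")
    merged = scores.merge(
        summaries.drop(columns=["industry"], errors="ignore"), on="company_id", how="left"
    )
    indicator_cols = [c for c in INDICATOR_DIRECTION if c in merged.columns]

    frames, notes = [], []
    for industry, sub in merged.groupby("industry", sort=True):
        sub = sub.sort_values(
            ["overall", "company_id"], ascending=[False, True], kind="mergesort"
        ).set_index("company_id")
        if len(sub) < 3:
            notes.append(f"{industry}: fewer than 3 companies, tertile banding skipped")
        for col in indicator_cols:
            sub[f"band_{col}"] = tertile_bands(sub[col], INDICATOR_DIRECTION[col])
        frames.append(sub.reset_index())
    report = pd.concat(frames, ignore_index=True)

    lines = ["Benchmark report (sorted by descending overall score per industry)", ""]
    for industry, sub in report.groupby("industry", sort=True):
        lines.append(f"== {industry} ==")
        for r in sub.itertuples():
            lines.append(
                f"  {r.company_id}: overall {r.overall:5.1f}% [{r.band_overall}]"
            )
        lines.append("")
    lines.extend(notes)
    return report, "\n".join(lines).rstrip() + "\n"
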