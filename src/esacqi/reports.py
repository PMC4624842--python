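"""Reporting utilities: response rates, extrapolation, study-style tables."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .aqpa import ReferenceStandard
from .attitude import IqorResult

__all__ = [
    "response_summary",
    "extrapolate_total_did",
    "format_item_screen",
    "format_indicator_table",
]


def response_summary(
    stage_counts: Mapping[str, int], total: int
) -> pd.DataFrame:
    """Cumulative survey response percentages by mailing stage.

    Percentages are reported to one decimal place, e.g. 1428 of 2100
    -> 68.0.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rows = []
    for stage, n in stage_counts.items():
        if not 0 <= n <= total:
            raise ValueError(f"stage {stage!r}: count {n} outside [0, {total}]")
        rows.append(
            {
                "stage": stage,
                "n_responders": int(n),
                "total": int(total),
                "pct": round(100.0 * n / total, 1),
            }
        )
    return pd.DataFrame(rows)


def extrapolate_total_did(
    primary_care_did: float, primary_care_share: float = 0.85
) -> float:
    """Scale a primary-care DID up to an all-settings total.

    With primary care accounting for a fraction *primary_care_share* of
    all prescriptions, total consumption is ``did / share`` (e.g. 15.65
    DID at an 85% share -> 18.41 DID).
    """
    if not 0 < primary_care_share <= 1:
        raise ValueError("primary_care_share must be in (0, 1]")
    if primary_care_did < 0:
        raise ValueError("DID must be >= 0")
    return primary_care_did / primary_care_share


def format_item_screen(
    results: Iterable[IqorResult],
    item_labels: Mapping[int, str] | None = None,
) -> str:
    """Aligned-text table of the per-item screen: quartiles, IqOR, CI, p."""
    labels = item_labels or {}
    header = (
        f"{'item':>4}  {'p25':>5} {'p50':>5} {'p75':>5}  "
        f"{'IqOR':>6}  {'95% CI':>14}  {'p':>7}  {'% change':>22}"
    )
    lines = [header, "-" * len(header)]
    for r in results:
        if r.status != "ok":
            lines.append(f"{r.item_id:>4}  [{r.status}]")
            continue
        ci = f"({r.ci_low:.2f}-{r.ci_high:.2f})"
        p = "<0.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
        pct = f"{r.pct_change:.0f}% {'+' if r.orientation == 'increase with exposure' else '-'}"
        lines.append(
            f"{r.item_id:>4}  {r.q25:>5.1f} {r.q50:>5.1f} {r.q75:>5.1f}  "
            f"{r.iqor:>6.2f}  {ci:>14}  {p:>7}  {pct:>22}"
        )
        if r.item_id in labels:
            lines.append(f"      {labels[r.item_id]}")
    lines.append(
        "orientation: + odds increase with exposure; - odds increase when "
        "exposure decreases (inverse IqOR rendering)"
    )
    return "\n".join(lines)


def format_indicator_table(
    report: pd.DataFrame, standard: ReferenceStandard | None = None
) -> str:
    """Aligned-text table of cohort indicator means vs the reference."""
    if standard is None:
        standard = ReferenceStandard.spain()
    header = (
        f"{'indicator':<14} {'reference':>9} {'cohort mean':>11} "
        f"{'% better':>9} {'n defined':>9}"
    )
    lines = [header, "-" * len(header)]
    for _, row in report.iterrows():
        mean = "NA" if pd.isna(row["mean_value"]) else f"{row['mean_value']:.2f}"
        pct = "NA" if pd.isna(row["pct_better"]) else f"{row['pct_better']:.1f}"
        lines.append(
            f"{row['indicator']:<14} {row['reference_value']:>9.2f} "
            f"{mean:>11} {pct:>9} {int(row['n_defined']):>9}"
        )
    return "\n".join(lines)
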