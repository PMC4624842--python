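"""Attitude/knowledge effects on prescribing quality: IqOR, ICC, item screen.

Physicians' knowledge and attitudes are measured once on 0-10 visual
analog scales (VAS).  Each item is screened in its own covariate-adjusted
random-intercept logistic model of the yearly AQPA outcome, and the
effect is reported as an interquartile odds ratio (IqOR): the odds ratio
for moving the exposure from its cohort 25th to its 75th percentile,

    IqOR = exp(beta * (q75 - q25)).

An IqOR below 1 is rendered as its inverse, 1/IqOR, read as the odds
increase in AQPA when the exposure *decreases* across the interquartile
range.  Questionnaire reliability uses the test-retest intraclass
correlation coefficient (two-way mixed effects, absolute agreement,
single measure); items with ICC <= 0.5 are dropped before the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glmm import RandomInterceptLogit, RandomInterceptLogitResults

__all__ = [
    "IqorResult",
    "exposure_quartiles",
    "compute_iqor",
    "percent_change",
    "icc_test_retest",
    "retain_items",
    "build_model_data",
    "run_item_screen",
    "screen_to_frame",
]

#: quantile rule matching a 0.5-step VAS grid
QUANTILE_METHOD = "median_unbiased"

DEFAULT_COVARIATES = ("on_call", "night_shifts", "mean_panel_k")


@dataclass(frozen=True)
class IqorResult:
    """Interquartile odds ratio of one attitude item with CI and rendering."""

    item_id: int
    q25: float
    q50: float
    q75: float
    iqor: float
    ci_low: float
    ci_high: float
    p_value: float
    pct_change: float
    orientation: str  # "increase with exposure" | "increase when exposure decreases"
    beta: float
    se: float
    status: str = "ok"  # "ok" | "degenerate" | "failed"

    @classmethod
    def failure(cls, item_id: int, status: str) -> "IqorResult":
        return cls(
            item_id=item_id, q25=np.nan, q50=np.nan, q75=np.nan,
            iqor=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
            pct_change=np.nan, orientation="", beta=np.nan, se=np.nan,
            status=status,
        )


def exposure_quartiles(scores: Iterable[float]) -> tuple[float, float, float]:
    """25th/50th/75th percentiles of the cohort exposure distribution."""
    arr = np.asarray(list(scores), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no scores to compute quartiles from")
    q = np.quantile(arr, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    return float(q[0]), float(q[1]), float(q[2])


def percent_change(iqor: float) -> tuple[float, str]:
    """Render an odds ratio as a non-negative percent change plus orientation.

    IqOR >= 1 -> (IqOR - 1) x 100, odds increase with the exposure;
    IqOR < 1 -> (1/IqOR - 1) x 100, odds increase when the exposure
    decreases from the 75th to the 25th percentile.  The magnitude is
    symmetric: an IqOR of x and of 1/x render identically.
    """
    if not np.isfinite(iqor) or iqor <= 0:
        raise ValueError(f"odds ratio must be positive, got {iqor}")
    if iqor >= 1.0:
        return (iqor - 1.0) * 100.0, "increase with exposure"
    return (1.0 / iqor - 1.0) * 100.0, "increase when exposure decreases"


def compute_iqor(
    fit: RandomInterceptLogitResults,
    scores: Iterable[float],
    item_id: int = 0,
    exposure_name: Optional[str] = None,
    alpha: float = 0.05,
) -> IqorResult:
    """Interquartile odds ratio from a fitted model and the exposure scores.

    *scores* is the cohort exposure distribution (one value per
    physician) from which the quartiles are taken.
    """
    if not fit.converged:
        raise ValueError("model fit did not converge; IqOR not computed")
    name = exposure_name or getattr(fit.model, "exposure_name", None)
    if name is None:
        name = fit.model.exog_names[1]
    beta, se = fit.coef(name)
    q25, q50, q75 = exposure_quartiles(scores)
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError(
            f"degenerate exposure for item {item_id}: q25 == q75 == {q25}"
        )
    z = norm.ppf(1 - alpha / 2)
    iqor = float(np.exp(beta * iqr))
    lo, hi = sorted(
        (float(np.exp((beta - z * se) * iqr)), float(np.exp((beta + z * se) * iqr)))
    )
    p = float(2 * norm.sf(abs(beta / se))) if se > 0 else np.nan
    pct, orientation = percent_change(iqor)
    return IqorResult(
        item_id=item_id, q25=q25, q50=q50, q75=q75,
        iqor=iqor, ci_low=lo, ci_high=hi, p_value=p,
        pct_change=pct, orientation=orientation, beta=beta, se=se,
    )


def icc_test_retest(pairs: Iterable[tuple[float, float]]) -> float:
    """Test-retest ICC: two-way mixed effects, absolute agreement, single measure.

    From the mean squares of a subjects x administrations decomposition
    with n subjects and k = 2 administrations:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

    where MS_R, MS_C, MS_E are the row (subject), column (administration)
    and residual mean squares.
    """
    data = np.asarray([(a, b) for a, b in pairs], dtype=float)
    data = data[~np.isnan(data).any(axis=1)]
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 complete test-retest pairs, got {n}")
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    if denom == 0:
        raise ValueError("degenerate mean squares: ICC undefined")
    return float((ms_r - ms_e) / denom)


def retain_items(
    icc_by_item: Mapping[int, float], threshold: float = 0.5
) -> list[int]:
    """Items whose ICC strictly exceeds the threshold (default 0.5)."""
    return sorted(item for item, icc in icc_by_item.items() if icc > threshold)


def item_iccs(attitudes: pd.DataFrame) -> dict[int, float]:
    """Per-item test-retest ICC from an attitude table with retest_score."""
    if "retest_score" not in attitudes.columns:
        raise ValueError("attitude table has no retest_score column")
    out: dict[int, float] = {}
    for item, sub in attitudes.groupby("item_id"):
        pairs = sub[["score", "retest_score"]].dropna()
        out[int(item)] = icc_test_retest(pairs.to_numpy())
    return out


def build_model_data(
    aqpa: pd.DataFrame,
    attitudes: pd.DataFrame,
    panels: pd.DataFrame,
    item_id: int,
) -> pd.DataFrame:
    """Join AQPA outcomes, one item's scores and covariates into model data.

    One row per physician-year with columns aqpa (0/1), score (constant
    within physician), on_call, night_shifts, mean_panel, mean_panel_k
    (panel in thousands, the unit used in the design matrix).
    """
    item = attitudes[attitudes["item_id"] == item_id]
    if item.empty:
        raise ValueError(f"no responses for item {item_id}")
    per_doc = item.drop_duplicates("physician_id").set_index("physician_id")
    if per_doc["score"].isna().all():
        raise ValueError(f"item {item_id} has no scores")
    mean_panel = panels.groupby("physician_id")["persons"].mean()
    data = aqpa[["physician_id", "year", "aqpa"]].copy()
    data["aqpa"] = data["aqpa"].astype(int)
    data["score"] = data["physician_id"].map(per_doc["score"])
    for cov in ("on_call", "night_shifts"):
        if cov in per_doc.columns:
            data[cov] = data["physician_id"].map(per_doc[cov]).astype(float)
        else:
            data[cov] = 0.0
    data["mean_panel"] = data["physician_id"].map(mean_panel)
    data["mean_panel_k"] = data["mean_panel"] / 1000.0
    return data.dropna(subset=["score", "mean_panel"]).reset_index(drop=True)


def run_item_screen(
    aqpa: pd.DataFrame,
    attitudes: pd.DataFrame,
    panels: pd.DataFrame,
    items: Optional[Sequence[int]] = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjusted: bool = True,
) -> list[IqorResult]:
    """One covariate-adjusted model per item; failures reported, not raised.

    Returns an :class:`IqorResult` per item (status "degenerate" for a
    constant exposure, "failed" for a non-converged fit); the screen
    continues past per-item failures.
    """
    if items is None:
        items = sorted(attitudes["item_id"].unique())
    results: list[IqorResult] = []
    covs = list(covariates) if adjusted else []
    for item in items:
        try:
            data = build_model_data(aqpa, attitudes, panels, item)
            scores = data.drop_duplicates("physician_id")["score"]
            q25, _, q75 = exposure_quartiles(scores)
            if q75 == q25:
                results.append(IqorResult.failure(int(item), "degenerate"))
                continue
            model = RandomInterceptLogit.from_dataframe(
                data, outcome="aqpa", exposure="score",
                covariates=covs, group="physician_id",
            )
            fit = model.fit()
            if not fit.converged:
                results.append(IqorResult.failure(int(item), "failed"))
                continue
            results.append(compute_iqor(fit, scores, item_id=int(item)))
        except (ValueError, np.linalg.LinAlgError):
            results.append(IqorResult.failure(int(item), "failed"))
    return results


def screen_to_frame(
    results: Iterable[IqorResult], bh_adjust: bool = False
) -> pd.DataFrame:
    """Tabulate screen results with the quartile/IqOR/CI/p column layout.

    With ``bh_adjust`` a Benjamini-Hochberg adjusted p-value column is
    appended (off by default; the screen reports per-item p-values).
    """
    rows = [
        {
            "item_id": r.item_id,
            "q25": r.q25, "q50": r.q50, "q75": r.q75,
            "iqor": r.iqor, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value,
            "pct_change": r.pct_change, "orientation": r.orientation,
            "status": r.status,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    if bh_adjust and len(frame):
        from statsmodels.stats.multitest import multipletests

        ok = frame["p_value"].notna()
        adj = np.full(len(frame), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                frame.loc[ok, "p_value"], method="fdr_bh"
            )[1]
        frame["p_bh"] = adj
    return frame
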