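"""The 12 ESAC antibiotic prescribing-quality indicators per physician-year.

Five volume indicators are expressed in DID (DDD per 1000 inhabitants per
day): total systemic antibacterials (J01) and the penicillin (J01C),
cephalosporin (J01D), macrolide/lincosamide/streptogramin (J01F) and
quinolone (J01M) subgroups.  Four are percentages of total J01 volume:
beta-lactamase-sensitive penicillins (J01CE), penicillin/beta-lactamase-
inhibitor combinations (J01CR), third/fourth-generation cephalosporins
(J01DD+DE) and fluoroquinolones (J01MA).  One is the unitless ratio of
broad- to narrow-spectrum consumption, and two are seasonal-variation
percentages — the winter-half-year excess over the summer half, on a
July-to-June year — for J01 and J01M.

An indicator whose denominator is zero is *undefined* and is carried as
such (``None`` in vectors, ``NaN``/"NA" in tabular output), never as 0.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .atc import AtcGroupMap, normalize_panels, normalize_prescriptions

__all__ = [
    "INDICATOR_NAMES",
    "IndicatorVector",
    "SeasonalYear",
    "compute_did",
    "compute_subclass_pct",
    "compute_bn_ratio",
    "compute_seasonal_variation",
    "compute_indicator_vector",
    "indicators_frame",
]

#: Column order of the 12 indicators everywhere in the package.
INDICATOR_NAMES = (
    "j01_did",
    "j01c_did",
    "j01d_did",
    "j01f_did",
    "j01m_did",
    "j01ce_pct",
    "j01cr_pct",
    "j01dd_de_pct",
    "j01ma_pct",
    "j01_bn_ratio",
    "j01_sv",
    "j01m_sv",
)

# (indicator, numerator group) for the DID and percentage indicators
_DID_GROUPS = (
    ("j01_did", "J01"),
    ("j01c_did", "J01C"),
    ("j01d_did", "J01D"),
    ("j01f_did", "J01F"),
    ("j01m_did", "J01M"),
)
_PCT_GROUPS = (
    ("j01ce_pct", "J01CE"),
    ("j01cr_pct", "J01CR"),
    ("j01dd_de_pct", "J01DD_DE"),
    ("j01ma_pct", "J01MA"),
)


@dataclass(frozen=True)
class SeasonalYear:
    """A July-to-June year split into winter and summer half-years.

    Winter = Oct-Dec of the start year plus Jan-Mar of the next; summer =
    Jul-Sep of the start year plus Apr-Jun of the next.  The two subsets
    partition the 12 months.
    """

    start_year: int

    @property
    def months(self) -> tuple[tuple[int, int], ...]:
        return self.winter_months + self.summer_months

    @property
    def winter_months(self) -> tuple[tuple[int, int], ...]:
        y = self.start_year
        return ((y, 10), (y, 11), (y, 12), (y + 1, 1), (y + 1, 2), (y + 1, 3))

    @property
    def summer_months(self) -> tuple[tuple[int, int], ...]:
        y = self.start_year
        return ((y, 7), (y, 8), (y, 9), (y + 1, 4), (y + 1, 5), (y + 1, 6))


@dataclass(frozen=True)
class IndicatorVector:
    """The 12 ESAC indicator values for one physician-year.

    ``None`` marks an undefined value (zero denominator).
    """

    physician_id: str
    year: int
    j01_did: Optional[float]
    j01c_did: Optional[float]
    j01d_did: Optional[float]
    j01f_did: Optional[float]
    j01m_did: Optional[float]
    j01ce_pct: Optional[float]
    j01cr_pct: Optional[float]
    j01dd_de_pct: Optional[float]
    j01ma_pct: Optional[float]
    j01_bn_ratio: Optional[float]
    j01_sv: Optional[float]
    j01m_sv: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def compute_did(ddd_total: float, persons: int, days: int) -> float:
    """DDD per 1000 inhabitants per day: ``ddd_total / (persons * days) * 1000``."""
    if persons <= 0:
        raise ValueError(f"persons must be > 0, got {persons}")
    if days <= 0:
        raise ValueError(f"days must be > 0, got {days}")
    if ddd_total < 0:
        raise ValueError(f"ddd_total must be >= 0, got {ddd_total}")
    return ddd_total / (persons * days) * 1000.0


def compute_subclass_pct(group_ddd: float, total_j01_ddd: float) -> Optional[float]:
    """Subgroup volume as a percentage of total J01; ``None`` when J01 is 0."""
    if total_j01_ddd == 0:
        return None
    if group_ddd > total_j01_ddd:
        raise ValueError(
            f"subgroup volume {group_ddd} exceeds total J01 volume "
            f"{total_j01_ddd}: group map violated upstream"
        )
    return 100.0 * group_ddd / total_j01_ddd


def compute_bn_ratio(broad_ddd: float, narrow_ddd: float) -> Optional[float]:
    """Broad/narrow-spectrum consumption ratio; ``None`` when narrow is 0."""
    if broad_ddd < 0 or narrow_ddd < 0:
        raise ValueError("DDD volumes must be >= 0")
    if narrow_ddd == 0:
        return None
    return broad_ddd / narrow_ddd


def seasonal_variation_from_totals(
    winter_ddd: float, summer_ddd: float
) -> Optional[float]:
    """``100 * (winter/summer - 1)``; ``None`` when summer volume is 0."""
    if summer_ddd == 0:
        return None
    return 100.0 * (winter_ddd / summer_ddd - 1.0)


def compute_seasonal_variation(
    records: pd.DataFrame,
    group: str,
    physician_id: str,
    seasonal_year: SeasonalYear,
    group_map: AtcGroupMap | None = None,
) -> Optional[float]:
    """Percent winter excess of *group* consumption for one physician."""
    from .atc import aggregate_ddd

    winter = aggregate_ddd(
        records, group, physician_id, seasonal_year.winter_months, group_map
    )
    summer = aggregate_ddd(
        records, group, physician_id, seasonal_year.summer_months, group_map
    )
    return seasonal_variation_from_totals(winter, summer)


def compute_indicator_vector(
    records: pd.DataFrame,
    persons: int,
    year: int,
    physician_id: str,
    group_map: AtcGroupMap | None = None,
    seasonal_year: SeasonalYear | None = None,
) -> IndicatorVector:
    """All 12 indicators for one physician-year.

    Calendar-year months feed the DID and percentage indicators; the
    seasonal pair uses *seasonal_year* (the July-June year assigned to
    this analysis year) and is undefined when it is ``None`` — e.g. for
    the first year of an extract, whose July-June year is not covered.
    """
    from .atc import aggregate_ddd

    if group_map is None:
        group_map = AtcGroupMap()
    cal_months = [(year, m) for m in range(1, 13)]
    days = days_in_year(year)

    totals = {
        g: aggregate_ddd(records, g, physician_id, cal_months, group_map)
        for g in (
            "J01", "J01C", "J01D", "J01F", "J01M",
            "J01CE", "J01CR", "J01DD_DE", "J01MA", "BROAD", "NARROW",
        )
    }
    values: dict[str, Optional[float]] = {}
    for name, g in _DID_GROUPS:
        values[name] = compute_did(totals[g], persons, days)
    for name, g in _PCT_GROUPS:
        values[name] = compute_subclass_pct(totals[g], totals["J01"])
    values["j01_bn_ratio"] = compute_bn_ratio(totals["BROAD"], totals["NARROW"])
    if seasonal_year is None:
        values["j01_sv"] = None
        values["j01m_sv"] = None
    else:
        values["j01_sv"] = compute_seasonal_variation(
            records, "J01", physician_id, seasonal_year, group_map
        )
        values["j01m_sv"] = compute_seasonal_variation(
            records, "J01M", physician_id, seasonal_year, group_map
        )
    return IndicatorVector(physician_id=physician_id, year=year, **values)


def indicators_frame(
    prescriptions: pd.DataFrame,
    panels: pd.DataFrame,
    group_map: AtcGroupMap | None = None,
    years: Iterable[int] | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Indicator table, one row per physician-year in the panel table.

    Vectorized over the whole cohort.  The seasonal indicators of
    analysis year Y use the July(Y-1)-June(Y) year and are undefined
    (NaN) for the earliest year of the analysis window, for which that
    window is not covered by the extract.

    Raises if any requested physician-year lacks a panel record.
    """
    if group_map is None:
        group_map = AtcGroupMap()
    if validate:
        prescriptions = normalize_prescriptions(prescriptions)
        panels = normalize_panels(panels)
    if years is not None:
        panels = panels[panels["year"].isin(set(years))].reset_index(drop=True)
    if panels.empty:
        raise ValueError("no physician-years to compute (empty panel table)")
    first_year = int(panels["year"].min())

    # tag every record with its group memberships once per unique code
    codes = prescriptions["atc"].unique()
    member = {
        g: {c: group_map.group(g).contains(c) for c in codes}
        for g in (
            "J01", "J01C", "J01D", "J01F", "J01M",
            "J01CE", "J01CR", "J01DD_DE", "J01MA", "BROAD", "NARROW",
        )
    }

    rx = prescriptions
    out = panels.copy()
    key = ["physician_id", "year"]

    def _sums(frame: pd.DataFrame, by: list[str]) -> pd.DataFrame:
        cols = {}
        for g, lookup in member.items():
            mask = frame["atc"].map(lookup).to_numpy(dtype=bool)
            cols[g] = frame["ddd_total"].where(mask, 0.0)
        tagged = frame[by].assign(**cols)
        return tagged.groupby(by, as_index=False).sum()

    annual = _sums(rx, key)
    out = out.merge(annual, on=key, how="left")
    group_cols = list(member)
    out[group_cols] = out[group_cols].fillna(0.0)

    days = out["year"].map(days_in_year)
    denom = out["persons"] * days
    for name, g in _DID_GROUPS:
        out[name] = out[g] / denom * 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, g in _PCT_GROUPS:
            out[name] = np.where(out["J01"] > 0, 100.0 * out[g] / out["J01"], np.nan)
        out["j01_bn_ratio"] = np.where(
            out["NARROW"] > 0, out["BROAD"] / out["NARROW"], np.nan
        )

    # seasonal pair: winter Oct(Y-1)-Mar(Y) vs summer Jul-Sep(Y-1)+Apr-Jun(Y)
    season_year = np.where(rx["month"] >= 7, rx["year"] + 1, rx["year"])
    is_winter = rx["month"].isin([10, 11, 12, 1, 2, 3]).to_numpy()
    j01_mask = rx["atc"].map(member["J01"]).to_numpy(dtype=bool)
    j01m_mask = rx["atc"].map(member["J01M"]).to_numpy(dtype=bool)
    seas = pd.DataFrame(
        {
            "physician_id": rx["physician_id"],
            "year": season_year,
            "half": np.where(is_winter, "winter", "summer"),
            "j01": rx["ddd_total"].where(j01_mask, 0.0),
            "j01m": rx["ddd_total"].where(j01m_mask, 0.0),
        }
    )
    half_sums = (
        seas.groupby(["physician_id", "year", "half"])[["j01", "j01m"]]
        .sum()
        .unstack("half")
    )
    half_sums.columns = [f"{g}_{h}" for g, h in half_sums.columns]
    for col in ("j01_winter", "j01_summer", "j01m_winter", "j01m_summer"):
        if col not in half_sums.columns:
            half_sums[col] = 0.0
    half_sums = half_sums.fillna(0.0).reset_index()
    out = out.merge(half_sums, on=key, how="left")
    for col in ("j01_winter", "j01_summer", "j01m_winter", "j01m_summer"):
        out[col] = out[col].fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["j01_sv"] = np.where(
            out["j01_summer"] > 0,
            100.0 * (out["j01_winter"] / out["j01_summer"] - 1.0),
            np.nan,
        )
        out["j01m_sv"] = np.where(
            out["j01m_summer"] > 0,
            100.0 * (out["j01m_winter"] / out["j01m_summer"] - 1.0),
            np.nan,
        )
    # boundary year: the July-June window is not inside the extract
    boundary = out["year"] == first_year
    out.loc[boundary, ["j01_sv", "j01m_sv"]] = np.nan

    result = out[key + ["persons"] + list(INDICATOR_NAMES)].copy()
    return result.sort_values(key).reset_index(drop=True)


def frame_row_to_vector(row: pd.Series) -> IndicatorVector:
    """Convert one row of :func:`indicators_frame` output to an IndicatorVector."""
    values = {
        name: (None if pd.isna(row[name]) else float(row[name]))
        for name in INDICATOR_NAMES
    }
    return IndicatorVector(
        physician_id=str(row["physician_id"]), year=int(row["year"]), **values
    )
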