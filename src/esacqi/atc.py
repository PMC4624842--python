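"""ATC code grammar, the J01 subgroup taxonomy, and DDD aggregation.

The WHO Anatomical Therapeutic Chemical (ATC) classification assigns each
drug a hierarchical code: one letter for the anatomical main group
(level 1, e.g. ``J``), two digits for the therapeutic subgroup (level 2,
``J01``), one letter each for the pharmacological and chemical subgroups
(levels 3-4, ``J01C``, ``J01CR``) and two digits for the substance
(level 5, ``J01CR02`` = amoxicillin/clavulanate).  Consumption volumes are
expressed in Defined Daily Doses (DDD), the assumed average adult
maintenance dose per day for the main indication.

This module validates codes, decides group membership by code-prefix, and
sums DDD volumes over arbitrary physician/time/group slices.  The group
map bundles the subgroups used by the ESAC prescribing-quality
indicators, including the broad- versus narrow-spectrum split:

* broad  = J01CR + J01DC + J01DD + (J01F minus erythromycin J01FA01)
* narrow = J01CE + J01DB + erythromycin (J01FA01)
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._codes import J01_CODES

__all__ = [
    "AtcCode",
    "AtcGroupMap",
    "PrescriptionRecord",
    "PanelRecord",
    "parse_atc",
    "in_group",
    "aggregate_ddd",
    "J01_CODES",
]

logger = logging.getLogger(__name__)

# ATC grammar by textual length: letter / letter+2 digits / +letter / +letter / +2 digits
_ATC_RE = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d\d$"),
    4: re.compile(r"^[A-Z]\d\d[A-Z]$"),
    5: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]$"),
    7: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]\d\d$"),
}


class AtcCode(str):
    """A validated, normalized ATC code (levels 1-5 of the hierarchy).

    Subclasses :class:`str`, so codes compare, hash and prefix-match as
    plain strings.
    """

    def __new__(cls, text: str) -> "AtcCode":
        if not isinstance(text, str) or not text.strip():
            raise ValueError("ATC code must be a non-empty string")
        norm = text.strip().upper()
        pattern = _ATC_RE.get(len(norm))
        if pattern is None or not pattern.match(norm):
            raise ValueError(
                f"malformed ATC code {text!r}: expected WHO ATC grammar "
                "(1/3/4/5/7 characters, alternating letter/digit blocks)"
            )
        return super().__new__(cls, norm)

    @property
    def level(self) -> int:
        return {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}[len(self)]

    def ancestors(self) -> tuple["AtcCode", ...]:
        """Codes of every higher level, outermost first (e.g. J, J01, J01C, J01CR)."""
        return tuple(
            AtcCode(self[:n]) for n in (1, 3, 4, 5) if n < len(self)
        )

    def is_within(self, prefix: str) -> bool:
        return self.startswith(prefix)


def parse_atc(text: str) -> AtcCode:
    """Parse and normalize *text* into a validated :class:`AtcCode`."""
    return AtcCode(text)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One physician-month-ATC cell of dispensed volume, in DDDs."""

    physician_id: str
    year: int
    month: int
    atc: AtcCode
    ddd_total: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1-12, got {self.month}")
        if self.ddd_total < 0:
            raise ValueError(f"ddd_total must be >= 0, got {self.ddd_total}")


@dataclass(frozen=True)
class PanelRecord:
    """Number of patients allocated to one physician in one year."""

    physician_id: str
    year: int
    persons: int

    def __post_init__(self) -> None:
        if self.persons <= 0:
            raise ValueError(f"persons must be > 0, got {self.persons}")


@dataclass(frozen=True)
class AtcGroup:
    """A code set defined by include prefixes minus exclude prefixes."""

    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def contains(self, code: str) -> bool:
        code = str(code)
        if any(code.startswith(p) for p in self.exclude):
            return False
        return any(code.startswith(p) for p in self.include)


@dataclass(frozen=True)
class AtcGroupMap:
    """Named J01 subgroup sets used by the quality indicators.

    ``BROAD`` and ``NARROW`` implement the ESAC broad/narrow-spectrum
    split; membership is decided by prefix so inputs may mix level-4 and
    level-5 substance codes.
    """

    groups: Mapping[str, AtcGroup] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def group(self, name: str) -> AtcGroup:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"unknown ATC group {name!r}; known groups: "
                f"{sorted(self.groups)}"
            ) from None

    def names(self) -> tuple[str, ...]:
        return tuple(self.groups)


_DEFAULT_GROUPS: dict[str, AtcGroup] = {
    "J01": AtcGroup(("J01",)),
    "J01C": AtcGroup(("J01C",)),
    "J01D": AtcGroup(("J01D",)),
    "J01F": AtcGroup(("J01F",)),
    "J01M": AtcGroup(("J01M",)),
    "J01CE": AtcGroup(("J01CE",)),
    "J01CR": AtcGroup(("J01CR",)),
    "J01DB": AtcGroup(("J01DB",)),
    "J01DC": AtcGroup(("J01DC",)),
    "J01DD": AtcGroup(("J01DD",)),
    "J01DE": AtcGroup(("J01DE",)),
    "J01DD_DE": AtcGroup(("J01DD", "J01DE")),
    "J01MA": AtcGroup(("J01MA",)),
    "J01FA01": AtcGroup(("J01FA01",)),
    "BROAD": AtcGroup(("J01CR", "J01DC", "J01DD", "J01F"), exclude=("J01FA01",)),
    "NARROW": AtcGroup(("J01CE", "J01DB", "J01FA01")),
}


def in_group(code: str | AtcCode, group: str, group_map: AtcGroupMap | None = None) -> bool:
    """True iff *code* (or equivalently one of its ancestors) is in *group* by prefix."""
    if group_map is None:
        group_map = AtcGroupMap()
    return group_map.group(group).contains(code)


def aggregate_ddd(
    records: pd.DataFrame | Iterable[PrescriptionRecord],
    group: str,
    physician_id: str | None = None,
    period: Iterable[tuple[int, int]] | None = None,
    group_map: AtcGroupMap | None = None,
) -> float:
    """Sum DDD volume over records matching a group, physician and period.

    Parameters
    ----------
    records
        Prescription records, either a DataFrame with columns
        ``physician_id, year, month, atc, ddd_total`` or an iterable of
        :class:`PrescriptionRecord`.
    group
        Named code set in the group map (e.g. ``"J01"``, ``"BROAD"``).
    physician_id
        Restrict to one physician; ``None`` sums over all.
    period
        Set of ``(year, month)`` pairs; ``None`` means all months.

    Returns 0.0 for an empty selection.
    """
    if group_map is None:
        group_map = AtcGroupMap()
    grp = group_map.group(group)

    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    if records.empty:
        return 0.0

    mask = records["atc"].map(grp.contains).to_numpy(dtype=bool)
    if physician_id is not None:
        mask &= (records["physician_id"] == physician_id).to_numpy(dtype=bool)
    if period is not None:
        period = set(period)
        ym = list(zip(records["year"].tolist(), records["month"].tolist()))
        mask &= pd.Series([p in period for p in ym]).to_numpy(dtype=bool)
    return float(records.loc[mask, "ddd_total"].sum())


def records_to_frame(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    """Materialize PrescriptionRecord objects as the canonical DataFrame."""
    rows = [
        (r.physician_id, r.year, r.month, str(r.atc), r.ddd_total)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["physician_id", "year", "month", "atc", "ddd_total"]
    )


def normalize_prescriptions(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an ingested prescription table.

    Codes are parsed and uppercased; duplicate
    ``(physician_id, year, month, atc)`` rows — common when dispensing
    extracts split lines — are summed with a logged warning rather than
    rejected.
    """
    required = ["physician_id", "year", "month", "atc", "ddd_total"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"prescription table missing columns: {missing}")
    out = frame.loc[:, required].copy()
    out["physician_id"] = out["physician_id"].astype(str)
    out["year"] = _as_int(out["year"], "year")
    out["month"] = _as_int(out["month"], "month")
    bad_month = out.index[(out["month"] < 1) | (out["month"] > 12)]
    if len(bad_month):
        raise ValueError(
            f"invalid month at row(s) {list(bad_month[:5])}: "
            f"{out.loc[bad_month[0], 'month']} (must be 1-12)"
        )
    out["atc"] = [str(parse_atc(a)) for a in out["atc"]]
    out["ddd_total"] = pd.to_numeric(out["ddd_total"])
    neg = out.index[out["ddd_total"] < 0]
    if len(neg):
        raise ValueError(f"negative ddd_total at row(s) {list(neg[:5])}")

    key = ["physician_id", "year", "month", "atc"]
    if out.duplicated(key).any():
        n = int(out.duplicated(key).sum())
        logger.warning("summing %d duplicate prescription row(s) on ingest", n)
        out = out.groupby(key, as_index=False)["ddd_total"].sum()
    return out.reset_index(drop=True)


def normalize_panels(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a patient-panel table (physician_id, year, persons)."""
    required = ["physician_id", "year", "persons"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"panel table missing columns: {missing}")
    out = frame.loc[:, required].copy()
    out["physician_id"] = out["physician_id"].astype(str)
    out["year"] = _as_int(out["year"], "year")
    out["persons"] = _as_int(out["persons"], "persons")
    bad = out.index[out["persons"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive panel size at row(s) {list(bad[:5])}")
    if out.duplicated(["physician_id", "year"]).any():
        raise ValueError("duplicate (physician_id, year) rows in panel table")
    return out.reset_index(drop=True)


def _as_int(series: pd.Series, name: str) -> pd.Series:
    values = pd.to_numeric(series)
    if (values != values.round()).any():
        raise ValueError(f"non-integer value in column {name!r}")
    return values.astype(int)
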