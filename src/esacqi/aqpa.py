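"""AQPA classification of physician-years against a national reference.

A physician-year shows Appropriate Quality Prescription of Antibiotics
(AQPA) when at least half (6 of 12) of its ESAC indicator values are
*better* than the national reference values.  "Better" is strict: a value
exactly equal to the reference does not count, and an undefined indicator
counts toward neither side (the >= 6 threshold is absolute, out of 12,
not out of the defined ones).

The default reference standard ships the Spanish national values with
lower-is-better for every indicator except the beta-lactamase-sensitive
penicillin share (J01CE %), where a higher share marks narrower-spectrum,
hence better, prescribing.  Both values and directions are overridable
from a TOML/CSV config block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .indicators import INDICATOR_NAMES, IndicatorVector

__all__ = [
    "ReferenceStandard",
    "AQPAResult",
    "is_better",
    "classify_aqpa",
    "classify_frame",
    "cohort_indicator_report",
    "SPAIN_REFERENCE_VALUES",
]

Direction = Literal["lower", "higher"]

#: Spanish national reference values for the 12 ESAC indicators.
SPAIN_REFERENCE_VALUES: dict[str, float] = {
    "j01_did": 19.68,
    "j01c_did": 12.31,
    "j01d_did": 1.56,
    "j01f_did": 1.90,
    "j01m_did": 2.42,
    "j01ce_pct": 0.50,
    "j01cr_pct": 38.70,
    "j01dd_de_pct": 2.80,
    "j01ma_pct": 12.0,
    "j01_bn_ratio": 56.89,
    "j01_sv": 125.8,
    "j01m_sv": 117.3,
}

_DEFAULT_DIRECTIONS: dict[str, Direction] = {
    name: ("higher" if name == "j01ce_pct" else "lower")
    for name in INDICATOR_NAMES
}


@dataclass(frozen=True)
class ReferenceStandard:
    """Per-indicator national reference value and direction-of-better."""

    values: Mapping[str, float]
    directions: Mapping[str, Direction]

    def __post_init__(self) -> None:
        missing = [n for n in INDICATOR_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"reference standard missing indicators: {missing}")
        missing = [n for n in INDICATOR_NAMES if n not in self.directions]
        if missing:
            raise ValueError(f"reference directions missing indicators: {missing}")
        bad = [
            n for n, d in self.directions.items() if d not in ("lower", "higher")
        ]
        if bad:
            raise ValueError(f"directions must be 'lower' or 'higher': {bad}")

    @classmethod
    def spain(cls) -> "ReferenceStandard":
        """The default Spanish national standard."""
        return cls(dict(SPAIN_REFERENCE_VALUES), dict(_DEFAULT_DIRECTIONS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceStandard":
        """Build from a table with columns indicator, reference_value, better_direction."""
        required = {"indicator", "reference_value", "better_direction"}
        if not required.issubset(frame.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        values = dict(zip(frame["indicator"], frame["reference_value"].astype(float)))
        directions = dict(zip(frame["indicator"], frame["better_direction"]))
        return cls(values, directions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": list(INDICATOR_NAMES),
                "reference_value": [self.values[n] for n in INDICATOR_NAMES],
                "better_direction": [self.directions[n] for n in INDICATOR_NAMES],
            }
        )


@dataclass(frozen=True)
class AQPAResult:
    """Better/worse/undefined indicator counts and the binary AQPA outcome."""

    physician_id: str
    year: int
    n_better: int
    n_worse: int
    n_undefined: int
    aqpa: bool

    def __post_init__(self) -> None:
        assert self.n_better + self.n_worse + self.n_undefined == len(INDICATOR_NAMES)


def is_better(
    value: Optional[float], reference: float, direction: Direction
) -> Literal["better", "worse", "undefined"]:
    """Compare one indicator value to its reference.

    Strict inequality in the better direction; equality is "worse";
    an undefined (None/NaN) value is "undefined".
    """
    if direction not in ("lower", "higher"):
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "undefined"
    if direction == "lower":
        return "better" if value < reference else "worse"
    return "better" if value > reference else "worse"


def classify_aqpa(
    vector: IndicatorVector, standard: ReferenceStandard | None = None
) -> AQPAResult:
    """Count better-than-reference indicators and apply the >= 6 rule."""
    if standard is None:
        standard = ReferenceStandard.spain()
    counts = {"better": 0, "worse": 0, "undefined": 0}
    for name in INDICATOR_NAMES:
        status = is_better(
            getattr(vector, name), standard.values[name], standard.directions[name]
        )
        counts[status] += 1
    return AQPAResult(
        physician_id=vector.physician_id,
        year=vector.year,
        n_better=counts["better"],
        n_worse=counts["worse"],
        n_undefined=counts["undefined"],
        aqpa=counts["better"] >= 6,
    )


def classify_frame(
    indicators: pd.DataFrame, standard: ReferenceStandard | None = None
) -> pd.DataFrame:
    """Classify every row of an indicator table.

    Returns columns physician_id, year, n_better, n_worse, n_undefined, aqpa.
    """
    if standard is None:
        standard = ReferenceStandard.spain()
    n_better = np.zeros(len(indicators), dtype=int)
    n_undef = np.zeros(len(indicators), dtype=int)
    for name in INDICATOR_NAMES:
        vals = indicators[name].to_numpy(dtype=float)
        undef = np.isnan(vals)
        ref = standard.values[name]
        if standard.directions[name] == "lower":
            better = vals < ref
        else:
            better = vals > ref
        n_better += np.where(undef, 0, better.astype(int))
        n_undef += undef.astype(int)
    out = indicators[["physician_id", "year"]].copy()
    out["n_better"] = n_better
    out["n_worse"] = len(INDICATOR_NAMES) - n_better - n_undef
    out["n_undefined"] = n_undef
    out["aqpa"] = n_better >= 6
    return out


def cohort_indicator_report(
    indicators: pd.DataFrame, standard: ReferenceStandard | None = None
) -> pd.DataFrame:
    """Per-indicator share of physician-years beating the reference.

    Returns one row per indicator with the reference value, number of
    defined physician-years, and ``pct_better`` = 100 x better/defined
    (NaN when no physician-year has the indicator defined).
    """
    if standard is None:
        standard = ReferenceStandard.spain()
    if len(indicators) == 0:
        raise ValueError("empty indicator collection")
    rows = []
    for name in INDICATOR_NAMES:
        vals = indicators[name].to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        ref = standard.values[name]
        if standard.directions[name] == "lower":
            better = (vals < ref) & defined
        else:
            better = (vals > ref) & defined
        n_def = int(defined.sum())
        rows.append(
            {
                "indicator": name,
                "reference_value": ref,
                "better_direction": standard.directions[name],
                "n_defined": n_def,
                "mean_value": float(np.nanmean(vals)) if n_def else np.nan,
                "pct_better": (100.0 * better.sum() / n_def) if n_def else np.nan,
            }
        )
    return pd.DataFrame(rows)
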