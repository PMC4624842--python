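"""Shared fixtures: small random cohorts and an independent indicator oracle.

The oracle reimplements the 12 indicators with per-record Python loops
and its own prefix rules, deliberately sharing no code with the package.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd
import pytest

# --- independent brute-force oracle -----------------------------------

_BROAD_PREFIXES = ("J01CR", "J01DC", "J01DD", "J01F")
_NARROW_PREFIXES = ("J01CE", "J01DB", "J01FA01")


def _oracle_member(code: str, prefixes, exclude=()) -> bool:
    if any(code.startswith(e) for e in exclude):
        return False
    return any(code.startswith(p) for p in prefixes)


def _oracle_sum(records, prefixes, physician, months, exclude=()):
    total = 0.0
    for rec in records:
        if rec["physician_id"] != physician:
            continue
        if (rec["year"], rec["month"]) not in months:
            continue
        if _oracle_member(rec["atc"], prefixes, exclude):
            total += rec["ddd_total"]
    return total


def oracle_indicator_vector(records, persons, physician, year, with_seasonal):
    """All 12 indicators by naive per-record loops; None = undefined."""
    months = {(year, m) for m in range(1, 13)}
    days = 366 if calendar.isleap(year) else 365

    def s(prefixes, exclude=()):
        return _oracle_sum(records, prefixes, physician, months, exclude)

    j01 = s(("J01",))
    out = {
        "j01_did": j01 / (persons * days) * 1000.0,
        "j01c_did": s(("J01C",)) / (persons * days) * 1000.0,
        "j01d_did": s(("J01D",)) / (persons * days) * 1000.0,
        "j01f_did": s(("J01F",)) / (persons * days) * 1000.0,
        "j01m_did": s(("J01M",)) / (persons * days) * 1000.0,
    }
    for name, prefixes in (
        ("j01ce_pct", ("J01CE",)),
        ("j01cr_pct", ("J01CR",)),
        ("j01dd_de_pct", ("J01DD", "J01DE")),
        ("j01ma_pct", ("J01MA",)),
    ):
        out[name] = 100.0 * s(prefixes) / j01 if j01 > 0 else None
    narrow = s(_NARROW_PREFIXES)
    broad = s(_BROAD_PREFIXES, exclude=("J01FA01",))
    out["j01_bn_ratio"] = broad / narrow if narrow > 0 else None
    if not with_seasonal:
        out["j01_sv"] = None
        out["j01m_sv"] = None
    else:
        sy = year - 1
        winter = {(sy, 10), (sy, 11), (sy, 12), (year, 1), (year, 2), (year, 3)}
        summer = {(sy, 7), (sy, 8), (sy, 9), (year, 4), (year, 5), (year, 6)}
        for name, prefixes in (("j01_sv", ("J01",)), ("j01m_sv", ("J01M",))):
            w = _oracle_sum(records, prefixes, physician, winter)
            s_ = _oracle_sum(records, prefixes, physician, summer)
            out[name] = 100.0 * (w / s_ - 1.0) if s_ > 0 else None
    return out


@pytest.fixture
def oracle():
    return oracle_indicator_vector


# --- random small cohorts ----------------------------------------------

_CODE_POOL = (
    "J01CR02", "J01CE02", "J01CA04", "J01DB01", "J01DC02", "J01DD04",
    "J01DE01", "J01FA01", "J01FA09", "J01FF01", "J01MA02", "J01MB04",
    "J01AA02", "J01EE01",
)


def make_random_cohort(rng: np.random.Generator, n_physicians=3, years=(2008, 2009)):
    """Sparse random prescription/panel tables with integer DDD volumes."""
    records = []
    for i in range(n_physicians):
        doc = f"D{i}"
        for year in years:
            for month in range(1, 13):
                for code in rng.choice(_CODE_POOL, size=rng.integers(0, 4), replace=False):
                    records.append(
                        {
                            "physician_id": doc,
                            "year": int(year),
                            "month": month,
                            "atc": str(code),
                            "ddd_total": float(rng.integers(0, 40)),
                        }
                    )
    prescriptions = pd.DataFrame(
        records,
        columns=["physician_id", "year", "month", "atc", "ddd_total"],
    )
    panels = pd.DataFrame(
        [
            {"physician_id": f"D{i}", "year": int(y), "persons": int(rng.integers(200, 2500))}
            for i in range(n_physicians)
            for y in years
        ]
    )
    return prescriptions, panels


@pytest.fixture
def random_cohort_factory():
    return make_random_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 120-physician synthetic cohort, shared per session."""
    from esacqi.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_physicians=120, seed=42))
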