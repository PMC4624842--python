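"""Indicator formulas, the per-physician-year engine, and its invariants."""

import numpy as np
import pandas as pd
import pytest

from esacqi.indicators import (
    INDICATOR_NAMES,
    SeasonalYear,
    compute_bn_ratio,
    compute_did,
    compute_indicator_vector,
    compute_subclass_pct,
    indicators_frame,
    seasonal_variation_from_totals,
)


class TestFormulas:
    @pytest.mark.parametrize(
        "ddd, persons, days, expected",
        [
            (5713.25, 1000, 365, 15.65),
            (0.0, 1500, 365, 0.0),
            (7300.0, 1000, 365, 20.0),
        ],
    )
    def test_did(self, ddd, persons, days, expected):
        assert compute_did(ddd, persons, days) == pytest.approx(expected, abs=0.005)

    def test_did_rejects_bad_denominators(self):
        with pytest.raises(ValueError):
            compute_did(10.0, 0, 365)
        with pytest.raises(ValueError):
            compute_did(10.0, 1000, 0)

    def test_subclass_pct(self):
        assert compute_subclass_pct(41.9, 100.0) == pytest.approx(41.9)
        assert compute_subclass_pct(0.0, 50.0) == 0.0
        assert compute_subclass_pct(50.0, 0.0) is None
        with pytest.raises(ValueError):
            compute_subclass_pct(60.0, 50.0)

    def test_bn_ratio(self):
        assert compute_bn_ratio(110.0, 50.0) == pytest.approx(2.2)
        assert compute_bn_ratio(0.0, 10.0) == 0.0
        assert compute_bn_ratio(10.0, 0.0) is None

    @pytest.mark.parametrize(
        "winter, summer, expected",
        [(240.0, 200.0, 20.0), (200.0, 200.0, 0.0), (452.0, 200.0, 126.0)],
    )
    def test_seasonal_variation(self, winter, summer, expected):
        assert seasonal_variation_from_totals(winter, summer) == pytest.approx(expected)

    def test_seasonal_variation_undefined_without_summer_volume(self):
        assert seasonal_variation_from_totals(100.0, 0.0) is None


class TestSeasonalYear:
    def test_winter_summer_partition_the_year(self):
        sy = SeasonalYear(2008)
        assert set(sy.winter_months) | set(sy.summer_months) == set(sy.months)
        assert set(sy.winter_months) & set(sy.summer_months) == set()
        assert len(sy.months) == 12
        assert (2008, 10) in sy.winter_months
        assert (2009, 4) in sy.summer_months


def _hand_fixture():
    """12 months of known volumes for one physician in 2009 (plus H2 2008)."""
    rows = []
    # 2009 calendar year: 100 DDD amox/clav + 10 DDD erythromycin per month,
    # 20 DDD ciprofloxacin in Jan-Mar only
    for m in range(1, 13):
        rows.append(("doc", 2009, m, "J01CR02", 100.0))
        rows.append(("doc", 2009, m, "J01FA01", 10.0))
    for m in (1, 2, 3):
        rows.append(("doc", 2009, m, "J01MA02", 20.0))
    # H2 2008 to complete the July 2008 - June 2009 seasonal year
    for m in (7, 8, 9):
        rows.append(("doc", 2008, m, "J01CR02", 50.0))
    for m in (10, 11, 12):
        rows.append(("doc", 2008, m, "J01CR02", 90.0))
    return pd.DataFrame(
        rows, columns=["physician_id", "year", "month", "atc", "ddd_total"]
    )


class TestVector:
    def test_hand_computed_fixture(self):
        records = _hand_fixture()
        vec = compute_indicator_vector(
            records, persons=1000, year=2009, physician_id="doc",
            seasonal_year=SeasonalYear(2008),
        )
        # hand arithmetic: annual J01 = 12*110 + 60 = 1380 DDD over 365 days
        assert vec.j01_did == pytest.approx(1380 / 1000 / 365 * 1000)
        assert vec.j01c_did == pytest.approx(1200 / 365)
        assert vec.j01f_did == pytest.approx(120 / 365)
        assert vec.j01m_did == pytest.approx(60 / 365)
        assert vec.j01d_did == 0.0
        assert vec.j01cr_pct == pytest.approx(100 * 1200 / 1380)
        assert vec.j01ce_pct == 0.0
        assert vec.j01ma_pct == pytest.approx(100 * 60 / 1380)
        assert vec.j01dd_de_pct == 0.0
        # broad = all J01CR; narrow = erythromycin only
        assert vec.j01_bn_ratio == pytest.approx(1200 / 120)
        # winter Oct-Dec 2008 (3*90) + Jan-Mar 2009 (3*110 + 60) = 660
        # summer Jul-Sep 2008 (3*50) + Apr-Jun 2009 (3*110) = 480
        assert vec.j01_sv == pytest.approx(100 * (660 / 480 - 1))
        # quinolones only appear in winter -> summer volume 0, undefined
        assert vec.j01m_sv is None

    def test_zero_prescriptions_year(self):
        records = pd.DataFrame(
            [], columns=["physician_id", "year", "month", "atc", "ddd_total"]
        )
        vec = compute_indicator_vector(
            records, persons=1200, year=2009, physician_id="doc",
            seasonal_year=SeasonalYear(2008),
        )
        for name in ("j01_did", "j01c_did", "j01d_did", "j01f_did", "j01m_did"):
            assert getattr(vec, name) == 0.0
        for name in (
            "j01ce_pct", "j01cr_pct", "j01dd_de_pct", "j01ma_pct",
            "j01_bn_ratio", "j01_sv", "j01m_sv",
        ):
            assert getattr(vec, name) is None


class TestEngine:
    def test_matches_brute_force_oracle(self, oracle, random_cohort_factory):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rx, panels = random_cohort_factory(rng)
            frame = indicators_frame(rx, panels)
            for _, row in frame.iterrows():
                expected = oracle(
                    rx.to_dict("records"),
                    int(row["persons"]),
                    row["physician_id"],
                    int(row["year"]),
                    with_seasonal=row["year"] != 2008,
                )
                for name in INDICATOR_NAMES:
                    got = row[name]
                    if expected[name] is None:
                        assert np.isnan(got), (name, row["physician_id"])
                    else:
                        assert got == expected[name], (name, row["physician_id"])

    def test_scale_equivariance(self, random_cohort_factory):
        rng = np.random.default_rng(11)
        rx, panels = random_cohort_factory(rng)
        base = indicators_frame(rx, panels)
        doubled = rx.assign(ddd_total=rx["ddd_total"] * 2)
        scaled = indicators_frame(doubled, panels)
        for name in ("j01_did", "j01c_did", "j01d_did", "j01f_did", "j01m_did"):
            assert np.allclose(scaled[name], base[name] * 2, equal_nan=True)
        for name in (
            "j01ce_pct", "j01cr_pct", "j01dd_de_pct", "j01ma_pct",
            "j01_bn_ratio", "j01_sv", "j01m_sv",
        ):
            assert np.allclose(
                scaled[name], base[name], equal_nan=True
            ), name

    def test_subgroup_dids_bounded_by_total(self, random_cohort_factory):
        rng = np.random.default_rng(13)
        for _ in range(10):
            rx, panels = random_cohort_factory(rng)
            frame = indicators_frame(rx, panels)
            subtotal = (
                frame["j01c_did"] + frame["j01d_did"]
                + frame["j01f_did"] + frame["j01m_did"]
            )
            assert (subtotal <= frame["j01_did"] + 1e-9).all()

    def test_boundary_year_seasonal_undefined(self, random_cohort_factory):
        rng = np.random.default_rng(17)
        rx, panels = random_cohort_factory(rng, years=(2008, 2009, 2010))
        frame = indicators_frame(rx, panels)
        first = frame[frame["year"] == 2008]
        assert first["j01_sv"].isna().all()
        assert first["j01m_sv"].isna().all()

    def test_missing_panel_raises(self, random_cohort_factory):
        rng = np.random.default_rng(19)
        rx, panels = random_cohort_factory(rng)
        with pytest.raises(ValueError, match="empty panel"):
            indicators_frame(rx, panels.iloc[0:0])
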