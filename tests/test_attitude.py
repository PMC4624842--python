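"""IqOR computation and rendering, ICC item retention, and the item screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esacqi.attitude import (
    build_model_data,
    compute_iqor,
    exposure_quartiles,
    icc_test_retest,
    item_iccs,
    percent_change,
    retain_items,
    run_item_screen,
    screen_to_frame,
)
from esacqi.glmm import RandomInterceptLogit
from esacqi.simulate import simulate_model_data


class TestPercentChange:
    @pytest.mark.parametrize(
        "iqor, pct, orientation",
        [
            (2.19, 119.0, "increase with exposure"),
            (0.60, 200.0 / 3.0, "increase when exposure decreases"),
            (0.75, 100.0 / 3.0, "increase when exposure decreases"),
            (1.0, 0.0, "increase with exposure"),
        ],
    )
    def test_published_style_renderings(self, iqor, pct, orientation):
        got_pct, got_orient = percent_change(iqor)
        assert got_pct == pytest.approx(pct)
        assert got_orient == orientation

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            percent_change(0.0)
        with pytest.raises(ValueError):
            percent_change(-1.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.01, 100.0))
    def test_magnitude_symmetric_under_inversion(self, x):
        assert percent_change(x)[0] == pytest.approx(
            percent_change(1.0 / x)[0], rel=1e-9
        )


class TestIqor:
    def _fit(self, data):
        return RandomInterceptLogit.from_dataframe(
            data, outcome="aqpa", exposure="score", group="physician_id"
        ).fit()

    def test_known_beta_and_unit_iqr(self):
        d = simulate_model_data(600, 3, beta_exposure=-0.3, seed=2)
        fit = self._fit(d)
        scores = np.array([0.0, 1.0] * 50)  # IQR exactly 1
        res = compute_iqor(fit, scores, item_id=1)
        beta, _ = fit.coef("score")
        assert res.iqor == pytest.approx(np.exp(beta))
        assert res.ci_low <= res.iqor <= res.ci_high

    def test_beta_zero_gives_unit_iqor(self):
        d = simulate_model_data(400, 3, beta_exposure=-0.2, seed=4)
        fit = self._fit(d)
        fit.params[1] = 0.0  # force a null exposure coefficient
        res = compute_iqor(fit, d["score"], item_id=1)
        assert res.iqor == pytest.approx(1.0)
        assert res.pct_change == pytest.approx(0.0)

    def test_invariant_under_exposure_rescaling(self):
        d = simulate_model_data(800, 3, beta_exposure=-0.25, seed=6)
        res1 = compute_iqor(self._fit(d), d["score"], item_id=1)
        d2 = d.assign(score=d["score"] * 2.0)
        res2 = compute_iqor(self._fit(d2), d2["score"], item_id=1)
        assert res2.iqor == pytest.approx(res1.iqor, rel=1e-4)
        assert res2.ci_low == pytest.approx(res1.ci_low, rel=1e-3)

    def test_degenerate_exposure_raises(self):
        d = simulate_model_data(400, 3, beta_exposure=-0.2, seed=8)
        fit = self._fit(d)
        with pytest.raises(ValueError, match="degenerate"):
            compute_iqor(fit, np.full(100, 5.0), item_id=3)

    def test_quartiles_use_median_unbiased_rule(self):
        scores = np.array([0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 9.0])
        expected = np.quantile(scores, [0.25, 0.5, 0.75], method="median_unbiased")
        assert exposure_quartiles(scores) == pytest.approx(tuple(expected))


class TestIcc:
    def test_perfect_retest_reproducibility(self):
        pairs = [(1.0, 1.0), (3.0, 3.0), (5.5, 5.5), (8.0, 8.0)]
        assert icc_test_retest(pairs) == pytest.approx(1.0)

    def test_independent_noise_has_near_zero_icc(self):
        rng = np.random.default_rng(10)
        pairs = np.column_stack([rng.uniform(0, 10, 5000), rng.uniform(0, 10, 5000)])
        assert abs(icc_test_retest(pairs)) < 0.05

    def test_hand_computed_six_pair_table(self):
        # mean-squares arithmetic done by hand for this table
        pairs = np.array(
            [(2.0, 3.0), (4.0, 4.5), (6.0, 5.0), (8.0, 7.0), (1.0, 2.0), (9.0, 9.5)]
        )
        n, k = 6, 2
        grand = pairs.mean()
        ms_r = k * ((pairs.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_c = n * ((pairs.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        ss_e = ((pairs - grand) ** 2).sum() - (n - 1) * ms_r / k * k - (k - 1) * ms_c / n * n
        ms_e = (
            ((pairs - grand) ** 2).sum()
            - k * ((pairs.mean(axis=1) - grand) ** 2).sum()
            - n * ((pairs.mean(axis=0) - grand) ** 2).sum()
        ) / ((n - 1) * (k - 1))
        expected = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))
        assert icc_test_retest(pairs) == pytest.approx(expected)

    def test_agrees_with_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        truth = rng.uniform(0, 10, 40)
        pairs = np.column_stack(
            [truth + rng.normal(0, 1, 40), truth + rng.normal(0, 1, 40)]
        )
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["t1", "t2"], 40),
                "score": pairs.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc_test_retest(pairs) == pytest.approx(
            float(table.loc["ICC(A,1)", "ICC"]), abs=1e-9
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_test_retest([(1.0, 1.0), (2.0, 2.0)])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_test_retest([(5.0, 5.0)] * 10)


class TestRetention:
    def test_strictly_above_threshold(self):
        iccs = {1: 0.9, 2: 0.5, 3: 0.51, 4: 0.2}
        assert retain_items(iccs) == [1, 3]

    def test_all_retained_when_all_reliable(self):
        iccs = {i: 0.8 for i in range(1, 12)}
        assert retain_items(iccs) == list(range(1, 12))

    def test_eleven_of_sixteen_survive_generator_reliability(self, small_cohort):
        """The default generator makes exactly the 11 analysis items reproducible."""
        iccs = item_iccs(small_cohort.attitudes)
        assert len(iccs) == 16
        assert retain_items(iccs) == list(range(1, 12))


@pytest.fixture(scope="module")
def screened_cohort(small_cohort):
    from esacqi.aqpa import classify_frame
    from esacqi.indicators import indicators_frame

    ind = indicators_frame(small_cohort.prescriptions, small_cohort.panels)
    aqpa = classify_frame(ind)
    return small_cohort, aqpa


class TestScreen:
    def test_model_data_join(self, screened_cohort):
        cohort, aqpa = screened_cohort
        data = build_model_data(aqpa, cohort.attitudes, cohort.panels, item_id=5)
        assert set(data.columns) >= {
            "physician_id", "year", "aqpa", "score",
            "on_call", "night_shifts", "mean_panel", "mean_panel_k",
        }
        # exposure constant within physician, 1-3 rows each
        per_doc = data.groupby("physician_id")
        assert (per_doc["score"].nunique() == 1).all()
        assert per_doc.size().between(1, 3).all()

    def test_constant_item_reported_degenerate_and_screen_continues(self, screened_cohort):
        cohort, aqpa = screened_cohort
        att = cohort.attitudes.copy()
        att.loc[att["item_id"] == 5, "score"] = 7.0
        results = run_item_screen(aqpa, att, cohort.panels, items=[5, 11])
        by_item = {r.item_id: r for r in results}
        assert by_item[5].status == "degenerate"
        assert by_item[11].status == "ok"

    def test_row_count_equals_items_screened(self, screened_cohort):
        cohort, aqpa = screened_cohort
        results = run_item_screen(aqpa, cohort.attitudes, cohort.panels, items=[1, 5, 9])
        assert [r.item_id for r in results] == [1, 5, 9]
        frame = screen_to_frame(results, bh_adjust=True)
        assert "p_bh" in frame.columns and len(frame) == 3
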