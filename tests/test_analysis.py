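"""Outcome construction, pooled tests, counterfactuals, ancillary analyses."""

import numpy as np
import pandas as pd
import pytest

from dispatchtrial import (
    GeneratorConfig,
    pipeline,
    pooled_logistic,
    pooled_wilcoxon,
    power_proportions,
    random_baseline,
)
from dispatchtrial import analysis
from dispatchtrial.analysis import (
    AnalysisError,
    DegenerateOutcomeError,
    build_rcs_outcomes,
    calibration_check,
    drift_monitor,
    months_since_update,
    time_trends,
)


def _toy_inputs(news_map, prioritized_id, arm="control", model_top="A"):
    members = "|".join(news_map)
    events = pd.DataFrame(
        {
            "event_id": ["E0"], "rcs_id": ["R0"], "member_ids": [members],
            "arm": [arm], "month": [3], "time": [3.0], "seq": [0], "site": [1],
            "model_top_id": [model_top], "gap": [0.1], "confidence": ["high"],
        }
    )
    long = pd.DataFrame(
        {"event_id": "E0", "patient_id": list(news_map), "news": list(news_map.values())}
    )
    prio = pd.Series({"E0": prioritized_id})
    return long, events, prio


@pytest.mark.parametrize(
    "news_map,prio,correct,diff",
    [
        ({"A": 5, "B": 3}, "A", 1, 2.0),
        ({"A": 3, "B": 5}, "A", 0, -2.0),
        ({"A": 4, "B": 4}, "A", 1, 0.0),  # ties count as correct
    ],
)
def test_outcome_examples(news_map, prio, correct, diff):
    long, events, p = _toy_inputs(news_map, prio)
    out = build_rcs_outcomes(long, events, p)
    assert out.correct_news.iloc[0] == correct
    assert out.news_diff.iloc[0] == pytest.approx(diff)


def test_news_diff_rules_for_larger_rcs():
    long, events, p = _toy_inputs({"A": 6, "B": 4, "C": 2}, "A")
    out_mean = build_rcs_outcomes(long, events, p, news_diff_rule="mean")
    out_max = build_rcs_outcomes(long, events, p, news_diff_rule="max")
    assert out_mean.news_diff.iloc[0] == pytest.approx(3.0)
    assert out_max.news_diff.iloc[0] == pytest.approx(2.0)


def test_missing_dispatch_is_an_error():
    long, events, _ = _toy_inputs({"A": 5, "B": 3}, "A")
    with pytest.raises(AnalysisError):
        build_rcs_outcomes(long, events, pd.Series(dtype=object))


class TestPooledLogistic:
    def test_identical_datasets_collapse(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"y": rng.integers(0, 2, 300),
                          "x": rng.normal(size=300)})
        pooled = pooled_logistic([d, d, d], "y", ["x"])["x"]
        assert pooled.between_var == pytest.approx(0.0, abs=1e-12)
        import statsmodels.api as sm
        single = sm.Logit(d.y, sm.add_constant(d.x)).fit(disp=0)
        assert pooled.point == pytest.approx(single.params.iloc[1], rel=1e-5)

    def test_degenerate_outcome_raises(self):
        d = pd.DataFrame({"y": np.ones(50), "x": np.arange(50)})
        with pytest.raises(DegenerateOutcomeError):
            pooled_logistic([d], "y", ["x"])

    def test_separation_falls_back_to_penalized(self):
        d = pd.DataFrame({"x": np.r_[np.zeros(25), np.ones(25)],
                          "y": np.r_[np.zeros(25), np.ones(25)]})
        pooled = pooled_logistic([d, d], "y", ["x"])["x"]
        assert "penalized_fallback" in pooled.flags
        assert np.isfinite(pooled.point)

    def test_recovers_true_arm_effect(self):
        """Logistic arm effect recovered from binary data with known log-OR."""
        rng = np.random.default_rng(1)
        logor = 0.25
        ests = []
        for _ in range(60):
            arm = rng.integers(0, 2, 1200)
            p = 1 / (1 + np.exp(-(0.4 + logor * arm)))
            d = pd.DataFrame({"y": (rng.uniform(size=1200) < p).astype(int), "arm": arm})
            ests.append(pooled_logistic([d], "y", ["arm"])["arm"].point)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - logor) < 3 * se


class TestPooledWilcoxon:
    def test_all_tied_reported_as_such(self):
        out = pd.DataFrame({"arm": ["control", "intervention"] * 5,
                            "news_diff": 1.0})
        est = pooled_wilcoxon([out])
        assert "all_tied" in est.flags
        assert np.isnan(est.point)

    def test_signal_detected(self):
        rng = np.random.default_rng(2)
        outs = []
        for _ in range(3):
            outs.append(pd.DataFrame({
                "arm": ["control"] * 150 + ["intervention"] * 150,
                "news_diff": np.r_[rng.normal(0, 2, 150), rng.normal(1.0, 2, 150)],
            }))
        est = pooled_wilcoxon(outs)
        assert est.point > 2
        assert est.p_value < 0.01


class TestComplianceRates:
    def test_full_agreement(self):
        out = pd.DataFrame({"arm": ["intervention"] * 10 + ["control"] * 10,
                            "model_agreement": 1,
                            "confidence": ["high", "low"] * 10})
        rates = analysis.compliance_rates(out)
        assert rates["intervention"]["rate"] == 1.0
        assert rates["confidence_high"]["rate"] == 1.0

    def test_independent_decisions_near_half(self):
        rng = np.random.default_rng(3)
        out = pd.DataFrame({"arm": "control",
                            "model_agreement": rng.integers(0, 2, 4000),
                            "confidence": "low"}, index=range(4000))
        rates = analysis.compliance_rates(out)
        assert 0.47 <= rates["control"]["rate"] <= 0.53

    def test_default_run_control_agreement_in_band(self):
        cfg = GeneratorConfig(n_rcs=10000, seed=32)
        sim = pipeline.simulate(cfg)
        prio = analysis.observed_prioritized(sim.dispatch)
        ln = analysis.member_news(sim.vitals_true, sim.analyzed_events)
        out = build_rcs_outcomes(ln, sim.analyzed_events, prio)
        rates = analysis.compliance_rates(out)
        assert 0.50 <= rates["control"]["rate"] <= 0.58


class TestRandomBaseline:
    @pytest.mark.parametrize(
        "news_map,expected",
        [({"A": 5, "B": 3}, 0.5), ({"A": 4, "B": 4}, 1.0),
         ({"A": 2, "B": 2, "C": 3}, 1.0 / 3.0)],
    )
    def test_enumeration(self, news_map, expected):
        long, events, _ = _toy_inputs(news_map, list(news_map)[0])
        assert random_baseline([long], events) == pytest.approx(expected)

    def test_exhaustive_small_configurations(self):
        """Agreement with brute-force enumeration over all tie patterns, size <= 4."""
        from itertools import product

        for size in (2, 3, 4):
            for values in product(range(3), repeat=size):
                ids = [f"M{i}" for i in range(size)]
                news_map = dict(zip(ids, values))
                long, events, _ = _toy_inputs(news_map, ids[0])
                # brute force: average over each member being picked
                brute = np.mean([values[i] == max(values) for i in range(size)])
                assert random_baseline([long], events) == pytest.approx(brute)


def test_power_proportions():
    res = power_proportions(0.653, 0.703)
    assert res.n_per_group == pytest.approx(1367, abs=2)
    assert res.note != ""  # the planning discrepancy is flagged
    # halving the effect approximately quadruples n
    res_half = power_proportions(0.678 - 0.0125, 0.678 + 0.0125)
    assert 3.2 < res_half.n_per_group / res.n_per_group < 4.8
    div = power_proportions(0.5, 0.5)
    assert np.isinf(div.n_per_group) and "diverges" in div.note
    with pytest.raises(AnalysisError):
        power_proportions(0.0, 0.5)


class TestTimeTrends:
    def _outcomes(self, n=600, drift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        month = rng.integers(0, 12, n)
        arm = np.where(rng.uniform(size=n) < 0.5, "intervention", "control")
        p_agree = 1 / (1 + np.exp(-(1.0 + drift * month)))
        return pd.DataFrame({
            "arm": arm, "month": month,
            "model_agreement": (rng.uniform(size=n) < p_agree).astype(int),
            "correct_news": rng.integers(0, 2, n),
        })

    def test_stationary_slope_near_one(self):
        out = self._outcomes(n=1500, seed=7)
        res = time_trends([out, out])
        assert 0.9 <= res["intervention_compliance_trend"]["slope_or_per_month"] <= 1.1
        lo = res["control_accuracy_trend"]["ci_low"]
        hi = res["control_accuracy_trend"]["ci_high"]
        assert lo <= 1.0 <= hi

    def test_injected_drift_recovered(self):
        out = self._outcomes(n=2000, drift=-0.15, seed=2)
        res = time_trends([out])
        assert res["intervention_compliance_trend"]["slope_or_per_month"] < 1.0
        assert res["intervention_compliance_trend"]["p_value"] < 0.05

    def test_single_month_errors(self):
        out = self._outcomes(seed=3)
        out["month"] = 4
        with pytest.raises(AnalysisError):
            time_trends([out])

    def test_zero_variance_outcome_errors(self):
        out = self._outcomes(seed=4)
        out["model_agreement"] = 1
        with pytest.raises(DegenerateOutcomeError):
            time_trends([out])


class TestDrift:
    def _table(self, n_month=24, per=150, decay=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(n_month):
            a = rng.normal(size=per)
            strength = max(1.0 + decay * m, 0.0)
            score = strength * a + rng.normal(size=per)
            newsv = a + rng.normal(size=per)
            rows.append(pd.DataFrame({"month": m, "composite_score": score,
                                      "news": newsv}))
        return pd.concat(rows, ignore_index=True)

    def test_null_slope_covers_zero(self):
        res = drift_monitor(self._table(seed=5), update_months=())
        assert res["ci_low"] <= 0.0 <= res["ci_high"]

    def test_decaying_association_negative_slope(self):
        res = drift_monitor(self._table(decay=-0.04, seed=6), update_months=())
        assert res["slope_per_month"] < 0
        assert res["p_value"] < 0.05

    def test_update_resets_clock(self):
        months = np.arange(0, 20)
        msu = months_since_update(months, (10,))
        assert msu[9] == 9 and msu[10] == 0 and msu[19] == 9

    def test_sparse_months_excluded(self):
        t = self._table(n_month=6, per=150, seed=7)
        sparse = pd.DataFrame({"month": 99, "composite_score": [1.0] * 5,
                               "news": [2.0] * 5})
        res = drift_monitor(pd.concat([t, sparse], ignore_index=True),
                            update_months=())
        assert res["excluded_months"] == [99]


class TestCalibration:
    def _table(self, n=3000, shift_category=None, seed=0):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        cats = rng.choice([f"cat{i}" for i in range(8)], n)
        newsv = 3 + 2 * score + rng.normal(size=n)
        if shift_category:
            newsv = newsv + 2.0 * (cats == shift_category)
        return pd.DataFrame({
            "news": newsv, "composite_score": score,
            "age": rng.integers(18, 100, n),
            "sex": rng.choice(["female", "male"], n),
            "call_type": cats,
        })

    def test_well_calibrated_score_leaves_no_demographic_signal(self):
        res = calibration_check(self._table(seed=8))
        assert "age" not in res["significant_terms"]
        assert "composite_score" in res["significant_terms"]

    def test_category_shift_flagged(self):
        res = calibration_check(self._table(shift_category="cat3", seed=9))
        assert "call_type_cat3" in res["significant_terms"]

    def test_constant_score_degenerate_case(self):
        t = self._table(seed=10)
        t["composite_score"] = 0.7
        res = calibration_check(t)
        assert res["flags"]


class TestCounterfactualLimits:
    def test_full_compliance_idempotent_when_already_compliant(self, small_run):
        cfg, sim, imp, long_list, outs = small_run
        ev = sim.analyzed_events
        prio = analysis.observed_prioritized(sim.dispatch)
        # force prioritized = model_top everywhere in the intervention arm
        forced = analysis.full_compliance_prioritized(ev, prio)
        again = analysis.full_compliance_prioritized(ev, forced)
        pd.testing.assert_series_equal(forced, again)

    def test_blended_low_confidence_equals_observed(self, small_run):
        cfg, sim, imp, long_list, outs = small_run
        ev = sim.analyzed_events.copy()
        ev["confidence"] = "low"
        prio = analysis.observed_prioritized(sim.dispatch)
        blended = analysis.blended_prioritized(ev, prio)
        pd.testing.assert_series_equal(blended.sort_index(), prio.sort_index())

    def test_counterfactual_improves_when_model_better(self):
        """With an accurate model and poor nurses, full compliance helps."""
        cfg = GeneratorConfig(n_rcs=1500, seed=51, model_noise_sd=0.4,
                              nurse_noise_sd=8.0, nurse_vitals_weight=0.0,
                              compliance_prob=0.5)
        sim = pipeline.simulate(cfg)
        ev = sim.analyzed_events
        prio = analysis.observed_prioritized(sim.dispatch)
        ln = analysis.member_news(sim.vitals_true, ev)
        obs = build_rcs_outcomes(ln, ev, prio)
        cf = build_rcs_outcomes(
            ln, ev, analysis.full_compliance_prioritized(ev, prio))
        inter = obs.arm == "intervention"
        assert (cf.correct_news[inter].mean() > obs.correct_news[inter].mean())


def test_median_of_m_majority_vote(small_run):
    """Median-of-m sensitivity variant collapses to a majority vote."""
    from dispatchtrial.analysis import median_of_m_outcomes

    _, _, _, _, outs = small_run
    collapsed = median_of_m_outcomes(outs)
    assert set(collapsed.correct_news.unique()) <= {0, 1}
    votes = np.stack([o.correct_news.to_numpy() for o in outs]).mean(axis=0)
    assert ((votes >= 0.5).astype(int) == collapsed.correct_news.to_numpy()).all()
    with pytest.raises(AnalysisError):
        median_of_m_outcomes(outs[:1])
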