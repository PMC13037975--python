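"""Trial protocol engine tests: randomization, repeats, decisions, flow."""

import numpy as np
import pandas as pd
import pytest

from dispatchtrial import GeneratorConfig, Randomizer, pipeline, resolve_repeats
from dispatchtrial.engine import (
    EligibilityError,
    FlowReconciliationError,
    consort_flow,
    dispatcher_decision,
    exclude_optouts,
)
from dispatchtrial.analysis import build_rcs_outcomes, member_news, observed_prioritized


def _events(rows):
    """Build a minimal event frame from (member_ids, arm, time) tuples."""
    return pd.DataFrame(
        {
            "event_id": [f"E{i}" for i in range(len(rows))],
            "rcs_id": ["R0"] * len(rows),
            "member_ids": [r[0] for r in rows],
            "arm": [r[1] for r in rows],
            "month": 0,
            "time": [r[2] for r in rows],
            "seq": range(len(rows)),
            "model_top_id": [r[0].split("|")[0] for r in rows],
            "gap": 0.1,
        }
    )


class TestRandomizer:
    def test_repeat_set_same_arm(self):
        r = Randomizer(np.random.default_rng(0))
        arms = [r.randomize(["A", "B"]) for _ in range(3)]
        assert len(set(arms)) == 1
        # order of ids is irrelevant
        assert r.randomize(["B", "A"]) == arms[0]

    def test_small_sets_rejected(self):
        r = Randomizer(np.random.default_rng(0))
        with pytest.raises(EligibilityError):
            r.randomize(["A"])
        with pytest.raises(EligibilityError):
            r.randomize(["A", "A"])

    def test_marginal_allocation_is_one_to_one(self):
        r = Randomizer(np.random.default_rng(1))
        arms = [r.randomize([f"A{i}", f"B{i}"]) for i in range(10000)]
        k = sum(a == "intervention" for a in arms)
        # binomial 99% CI around 5000
        assert abs(k - 5000) < 2.576 * np.sqrt(10000 * 0.25)

    def test_reproducible_sequence(self):
        seqs = []
        for _ in range(2):
            r = Randomizer(np.random.default_rng(99))
            seqs.append([r.randomize([f"A{i}", f"B{i}"]) for i in range(50)])
        assert seqs[0] == seqs[1]


class TestResolveRepeats:
    def test_identical_set_keeps_last(self):
        ev = _events([("A|B", "control", 0.0), ("A|B", "control", 1.0)])
        resolved, viol = resolve_repeats(ev)
        assert list(resolved.event_id) == ["E1"]
        assert list(viol.event_id) == ["E0"]

    def test_grown_set_arm_disagreement_excludes_all(self):
        ev = _events([("A|B", "control", 0.0), ("A|B|C", "intervention", 1.0)])
        resolved, viol = resolve_repeats(ev)
        assert len(resolved) == 0
        assert set(viol.event_id) == {"E0", "E1"}

    def test_grown_set_same_arm_keeps_last(self):
        ev = _events([("A|B", "control", 0.0), ("A|B|C", "control", 1.0)])
        resolved, viol = resolve_repeats(ev)
        assert list(resolved.event_id) == ["E1"]
        assert list(viol.event_id) == ["E0"]

    def test_idempotent(self):
        ev = _events(
            [("A|B", "control", 0.0), ("A|B|C", "control", 1.0),
             ("X|Y", "intervention", 2.0)]
        )
        r1, v1 = resolve_repeats(ev)
        r2, v2 = resolve_repeats(r1)
        pd.testing.assert_frame_equal(r1.reset_index(drop=True), r2)
        assert len(v2) == 0


class TestDispatcherDecision:
    def test_full_compliance_always_model(self):
        rng = np.random.default_rng(0)
        nurse = {"A": 5.0, "B": 1.0}
        picks = {
            dispatcher_decision(["A", "B"], "intervention", "B", nurse, rng, 1.0)
            for _ in range(20)
        }
        assert picks == {"B"}

    def test_control_follows_nurse_signal(self):
        rng = np.random.default_rng(0)
        nurse = {"A": 5.0, "B": 1.0}
        picks = {
            dispatcher_decision(["A", "B"], "control", "B", nurse, rng, 1.0)
            for _ in range(20)
        }
        assert picks == {"A"}

    def test_noiseless_control_tracks_true_acuity(self):
        cfg = GeneratorConfig(n_rcs=400, nurse_noise_sd=0.0, nurse_vitals_weight=0.0,
                              repeat_randomization_prob=0.0,
                              optout_prob_per_patient=0.0, seed=31)
        sim = pipeline.simulate(cfg)
        prio = observed_prioritized(sim.dispatch)
        merged = sim.patients.set_index("patient_id")
        ev = sim.analyzed_events
        for rec in ev[ev.arm == "control"].itertuples(index=False):
            ids = rec.member_ids.split("|")
            top = max(ids, key=lambda p: merged.loc[p, "latent_acuity"])
            assert prio[rec.event_id] == top

    def test_default_intervention_agreement_near_calibration_target(self):
        cfg = GeneratorConfig(n_rcs=10000, seed=32)
        sim = pipeline.simulate(cfg)
        ev = sim.analyzed_events
        prio = observed_prioritized(sim.dispatch)
        ln = member_news(sim.vitals_true, ev)
        out = build_rcs_outcomes(ln, ev, prio)
        agree = out.loc[out.arm == "intervention", "model_agreement"].mean()
        assert 0.79 <= agree <= 0.83


class TestFlow:
    def test_no_exclusions_everything_analyzed(self):
        ev = _events([("A|B", "control", 0.0), ("C|D", "intervention", 1.0)])
        flow = consort_flow(ev, ev.iloc[0:0], ev)
        assert flow.analyzed_rcs == flow.randomized_rcs == 2
        assert flow.protocol_violation_rcs == flow.optout_excluded_rcs == 0

    def test_arithmetic(self):
        rows = [(f"A{i}|B{i}", "control", float(i)) for i in range(100)]
        ev = _events(rows)
        ev["rcs_id"] = [f"R{i}" for i in range(100)]
        viol = ev.iloc[:19]
        analyzed = ev.iloc[19 + 14:]
        flow = consort_flow(ev, viol, analyzed)
        assert flow.analyzed_rcs == 67
        assert flow.optout_excluded_rcs == 14

    def test_reconciliation_failure_raises(self):
        ev = _events([("A|B", "control", 0.0)])
        with pytest.raises(FlowReconciliationError):
            consort_flow(ev, ev, ev)  # violations + analyzed > randomized

    def test_full_run_reconciles(self, small_sim):
        _, sim = small_sim
        f = sim.flow
        assert (
            f["randomized_rcs"]
            == f["protocol_violation_rcs"] + f["optout_excluded_rcs"] + f["analyzed_rcs"]
        )
        assert sum(f["rcs_by_arm"].values()) == f["analyzed_rcs"]

    def test_all_optout_excludes_all(self):
        cfg = GeneratorConfig(n_rcs=30, optout_prob_per_patient=1.0, seed=33)
        sim = pipeline.simulate(cfg)
        assert sim.flow["analyzed_rcs"] == 0

    def test_violation_asymmetry_toward_control(self):
        # control-arm re-rolls dominate the protocol violations
        cfg = GeneratorConfig(n_rcs=4000, seed=34)
        sim = pipeline.simulate(cfg)
        first = sim.violations[sim.violations.seq == 0]
        assert (first.arm == "control").sum() > (first.arm == "intervention").sum()


def test_exclude_optouts_removes_affected_rcs(small_sim):
    _, sim = small_sim
    opted = set(sim.patients.loc[sim.patients.optout, "patient_id"])
    for mids in sim.analyzed_events.member_ids:
        assert not opted & set(mids.split("|"))
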