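"""Trial protocol engine.

Executes the randomized dispatch protocol on a synthetic cohort: each
resource-constrained situation (RCS) is randomized 1:1 to control or
intervention when the dispatcher presses "predict"; repeat randomizations
of the identical patient set deterministically return the prior arm;
dispatchers may re-roll (mostly after a control assignment) and sometimes
grow the comparison with a late-arriving patient, which creates the
protocol violations the analysis must resolve; the dispatcher then sends
the available ambulance to one patient (the *prioritized* patient) and the
rest wait.

Decision model: the nurses' preferred patient is the argmax of a perceived
severity signal (latent acuity + a weighted load on the realized vital-sign
deviation + noise).  Control-arm choices follow the nurses; intervention-
arm choices defer to the model's top-scored patient with probability
``compliance_prob`` and otherwise follow the nurses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .cohort import expected_news, news_conditional_sd


class EligibilityError(ValueError):
    """A comparison needs at least two members."""


class FlowReconciliationError(RuntimeError):
    """CONSORT flow counts failed to reconcile."""


MEMBER_SEP = "|"


def _join(ids) -> str:
    return MEMBER_SEP.join(ids)


def _split(s: str) -> list:
    return s.split(MEMBER_SEP)


class Randomizer:
    """1:1 Bernoulli arm allocation with repeat-set memory.

    Identical member sets (keyed on the sorted id set) always receive the
    arm drawn at their first randomization, mirroring the server-side
    repeat-randomization guard.
    """

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._memory: dict = {}

    def randomize(self, member_ids) -> str:
        ids = tuple(sorted(member_ids))
        if len(ids) < 2:
            raise EligibilityError("an RCS randomization requires >= 2 members")
        if len(set(ids)) != len(ids):
            raise EligibilityError("duplicate member ids in comparison")
        if ids not in self._memory:
            self._memory[ids] = "intervention" if self._rng.random() < 0.5 else "control"
        return self._memory[ids]


def randomize_rcs(member_ids, randomizer: Randomizer) -> str:
    """Functional wrapper over :class:`Randomizer.randomize`."""
    return randomizer.randomize(member_ids)


def nurse_signals(
    patients: pd.DataFrame, true_news: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """Perceived severity per patient as seen by the triaging nurses.

    latent acuity + nurse_vitals_weight * standardized NEWS residual +
    N(0, nurse_noise_sd).  The residual term represents genuine physiologic
    information gleaned from the call that the dispatch-data model cannot
    see; it is what allows nurse accuracy against NEWS to exceed what their
    (modest) agreement with the model alone would imply.
    """
    rng = config.rng("decisions")
    a = patients["latent_acuity"].to_numpy()
    resid = (true_news - expected_news(a, config)) / news_conditional_sd(a, config)
    noise = rng.normal(0.0, config.nurse_noise_sd, size=len(a))
    return a + config.nurse_vitals_weight * resid + noise


def simulate_events(
    patients: pd.DataFrame,
    rcs: pd.DataFrame,
    predictions: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Randomize every RCS, including dispatcher re-rolls.

    Returns the append-only randomization-event log, time-ordered.  A
    re-roll repeats the identical member set (harmless: the memory returns
    the same arm and only the last event is analyzed) or, with probability
    ``repeat_grow_prob``, adds the RCS's late-arrival candidate and
    re-randomizes the grown set, which draws a fresh arm and may create a
    protocol violation.
    """
    rng = config.rng("randomize")
    randomizer = Randomizer(rng)
    comp = predictions.set_index("patient_id")["composite_score"]

    members_by_rcs: dict = {}
    late_by_rcs: dict = {}
    for rid, grp in patients.groupby("rcs_id", sort=False):
        base = grp.loc[~grp.late_arrival, "patient_id"].tolist()
        members_by_rcs[rid] = base
        lates = grp.loc[grp.late_arrival, "patient_id"].tolist()
        late_by_rcs[rid] = lates[0] if lates else None

    rows = []
    eid = 0

    def _event(rid, ids, month, time, seq):
        nonlocal eid
        arm = randomizer.randomize(ids)
        scores = comp.loc[list(ids)]
        order = np.argsort(-scores.to_numpy())
        top = scores.index[order[0]]
        gap = float(scores.iloc[order[0]] - scores.iloc[order[1]])
        rows.append(
            {
                "event_id": f"E{eid:06d}",
                "rcs_id": rid,
                "member_ids": _join(ids),
                "arm": arm,
                "month": int(month),
                "time": float(time),
                "seq": seq,
                "model_top_id": top,
                "gap": gap,
            }
        )
        eid += 1
        return arm

    for rec in rcs.itertuples(index=False):
        ids = members_by_rcs[rec.rcs_id]
        arm = _event(rec.rcs_id, ids, rec.month, rec.time, 0)
        p_repeat = config.repeat_randomization_prob * (
            1.0 if arm == "control" else config.repeat_intervention_factor
        )
        if rng.random() < p_repeat:
            grow = rng.random() < config.repeat_grow_prob and late_by_rcs[rec.rcs_id]
            new_ids = ids + [late_by_rcs[rec.rcs_id]] if grow else ids
            _event(rec.rcs_id, new_ids, rec.month, rec.time + 1e-4, 1)

    return pd.DataFrame(rows)


def resolve_repeats(events: pd.DataFrame):
    """Apply the repeat-randomization analysis rule.

    Events are grouped by shared patients.  Within a group: identical
    member sets keep only the last event (earlier ones were never
    dispatched and are excluded); overlapping-but-unequal sets keep the
    last event only if every event in the group drew the same arm, and
    otherwise the whole group is excluded as protocol violations.
    Idempotent: resolving an already-resolved log changes nothing.

    Returns ``(resolved, violations)`` DataFrames.
    """
    ev = events.sort_values("time", kind="stable").reset_index(drop=True)
    # union-find over events sharing any patient
    parent = list(range(len(ev)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    seen: dict = {}
    for i, mids in enumerate(ev.member_ids):
        for pid in _split(mids):
            if pid in seen:
                union(seen[pid], i)
            seen[pid] = i

    groups: dict = {}
    for i in range(len(ev)):
        groups.setdefault(find(i), []).append(i)

    keep, viol = [], []
    for idxs in groups.values():
        sets = {frozenset(_split(ev.member_ids.iloc[i])) for i in idxs}
        arms = {ev.arm.iloc[i] for i in idxs}
        if len(idxs) == 1:
            keep.append(idxs[0])
        elif len(sets) == 1 or len(arms) == 1:
            keep.append(idxs[-1])
            viol.extend(idxs[:-1])
        else:
            viol.extend(idxs)
    resolved = ev.iloc[sorted(keep)].reset_index(drop=True)
    violations = ev.iloc[sorted(viol)].reset_index(drop=True)
    return resolved, violations


def dispatcher_decision(
    member_ids,
    arm: str,
    model_top_id: str,
    nurse_by_id: dict,
    rng: np.random.Generator,
    compliance_prob: float,
) -> str:
    """Pick the prioritized patient for one resolved comparison."""
    sig = np.array([nurse_by_id[pid] for pid in member_ids])
    top = np.flatnonzero(sig == sig.max())
    nurse_pick = member_ids[int(rng.choice(top))] if len(top) > 1 else member_ids[int(top[0])]
    if arm == "intervention" and rng.random() < compliance_prob:
        return model_top_id
    return nurse_pick


def simulate_dispatch(
    resolved: pd.DataFrame,
    patients: pd.DataFrame,
    nurse_sig: np.ndarray,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Dispatcher decisions + ambulance assignment order for resolved events.

    Only the ordering matters for the hypothesis tests; assignment delays
    are drawn from lognormals (median ~ 30 min for the prioritized patient)
    purely to furnish realistic-looking logs and descriptive tables.
    """
    rng = config.rng("decisions").spawn(1)[0]
    nurse_by_id = dict(zip(patients.patient_id, nurse_sig))
    rows = []
    for rec in resolved.itertuples(index=False):
        ids = _split(rec.member_ids)
        pick = dispatcher_decision(
            ids, rec.arm, rec.model_top_id, nurse_by_id, rng, config.compliance_prob
        )
        others = [p for p in ids if p != pick]
        rng.shuffle(others)
        delay = rng.lognormal(np.log(30.0), 0.45)
        rows.append(
            {
                "event_id": rec.event_id,
                "rcs_id": rec.rcs_id,
                "patient_id": pick,
                "assign_order": 0,
                "delay_min": round(float(delay), 1),
            }
        )
        for k, p in enumerate(others, start=1):
            rows.append(
                {
                    "event_id": rec.event_id,
                    "rcs_id": rec.rcs_id,
                    "patient_id": p,
                    "assign_order": k,
                    "delay_min": round(float(delay + rng.lognormal(np.log(14.0 * k), 0.5)), 1),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FlowCounts:
    """CONSORT-style participant flow accounting."""

    randomized_rcs: int
    protocol_violation_rcs: int
    optout_excluded_rcs: int
    analyzed_rcs: int
    rcs_by_arm: dict
    patients_by_arm: dict

    def as_dict(self) -> dict:
        return asdict(self)


def consort_flow(
    events: pd.DataFrame, violations: pd.DataFrame, analyzed: pd.DataFrame
) -> FlowCounts:
    """Reconcile the randomization, exclusion and analysis counts.

    ``analyzed`` is the resolved event table after opt-out exclusions.
    Raises :class:`FlowReconciliationError` if the stages do not add up.
    """
    randomized = len(events)
    n_viol = len(violations)
    resolved = randomized - n_viol
    n_analyzed = len(analyzed)
    optout_excluded = resolved - n_analyzed
    if optout_excluded < 0 or randomized != n_viol + optout_excluded + n_analyzed:
        raise FlowReconciliationError(
            f"flow does not reconcile: {randomized} randomized != {n_viol} violations "
            f"+ {optout_excluded} opt-out exclusions + {n_analyzed} analyzed"
        )
    rcs_by_arm = analyzed.arm.value_counts().to_dict()
    sizes = analyzed.member_ids.str.count(rf"\{MEMBER_SEP}") + 1
    patients_by_arm = (
        pd.DataFrame({"arm": analyzed.arm, "n": sizes}).groupby("arm")["n"].sum().to_dict()
    )
    return FlowCounts(
        randomized_rcs=randomized,
        protocol_violation_rcs=n_viol,
        optout_excluded_rcs=optout_excluded,
        analyzed_rcs=n_analyzed,
        rcs_by_arm={k: int(v) for k, v in rcs_by_arm.items()},
        patients_by_arm={k: int(v) for k, v in patients_by_arm.items()},
    )


def exclude_optouts(resolved: pd.DataFrame, patients: pd.DataFrame):
    """Drop resolved events containing any opted-out patient."""
    opted = set(patients.loc[patients.optout, "patient_id"])
    mask = resolved.member_ids.map(lambda s: any(p in opted for p in _split(s)))
    return resolved[~mask].reset_index(drop=True), resolved[mask].reset_index(drop=True)
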