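"""Human-readable report rendering.

Produces a cohort-description table (counts, medians with percentile
bootstrap CIs from 1,000 resamples) and a hypothesis-summary table from a
results dict, as both delimited and formatted text.  Missing analysis
blocks are skipped with a warning line rather than failing the render.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import news
from .engine import _split

_N_BOOT = 1000


def _boot_ci(values: np.ndarray, statistic, rng: np.random.Generator) -> tuple:
    if len(values) == 0:
        return (np.nan, np.nan, np.nan)
    est = statistic(values)
    idx = rng.integers(0, len(values), size=(_N_BOOT, len(values)))
    boots = np.array([statistic(values[i]) for i in idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(est), float(lo), float(hi)


def _fmt(est, lo, hi, nd=1):
    if np.isnan(est):
        return "-"
    return f"{round(est, nd):g} [{round(lo, nd):g}, {round(hi, nd):g}]"


def cohort_table(sim, imp=None, seed: int = 0) -> pd.DataFrame:
    """Arm-wise cohort description with bootstrap percentile CIs."""
    rng = np.random.default_rng(seed)
    events = sim.analyzed_events
    rows = {}
    member_map = []
    for rec in events.itertuples(index=False):
        for pid in _split(rec.member_ids):
            member_map.append((rec.event_id, rec.arm, pid))
    members = pd.DataFrame(member_map, columns=["event_id", "arm", "patient_id"])
    members = members.merge(sim.patients, on="patient_id")
    if imp is not None:
        scored = news.score_table(imp.tables[0].set_index("patient_id"))["news_total"]
        members["news"] = members.patient_id.map(scored)
    prio = sim.dispatch[sim.dispatch.assign_order == 0].merge(
        events[["event_id", "arm"]], on="event_id"
    )
    for arm in ("control", "intervention"):
        sub = members[members.arm == arm]
        n_rcs = int((events.arm == arm).sum())
        age = sub.age.to_numpy()
        fem = (sub.sex == "female").to_numpy(dtype=float) * 100
        med_age = _boot_ci(age, np.median, rng)
        pct_f = _boot_ci(fem, np.mean, rng)
        pdel = prio.loc[prio.arm == arm, "delay_min"].to_numpy()
        med_delay = _boot_ci(pdel, np.median, rng)
        col = {
            "Number of RCS included": str(n_rcs),
            "Number of patients included": str(len(sub)),
            "Median age": _fmt(*med_age),
            "Percent female": _fmt(*pct_f),
            "Median dispatch delay for prioritized patient (minutes)": _fmt(*med_delay),
        }
        if imp is not None:
            mean_news = _boot_ci(sub.news.to_numpy(dtype=float), np.mean, rng)
            col["Average NEWS"] = _fmt(*mean_news)
        rows[arm] = col
    table = pd.DataFrame(rows).reset_index(names="Characteristic")
    return table


def hypothesis_table(results: dict) -> pd.DataFrame:
    """Primary/secondary hypothesis summary rows from a results dict."""
    rows = []

    def _or_row(label, block):
        orr = block["odds_ratio"]
        rows.append(
            {
                "Hypothesis": label,
                "Result": (
                    f"OR {orr['or']:.2f} (95% CI [{orr['ci_low']:.2f}, "
                    f"{orr['ci_high']:.2f}], p = {orr['p_value']:.3f})"
                ),
            }
        )

    if "primary" in results:
        _or_row(
            "Primary: odds of prioritized patient having the highest NEWS "
            "greater in the intervention arm (pooled logistic regression)",
            results["primary"],
        )
    else:
        rows.append({"Hypothesis": "Primary", "Result": "WARNING: block missing"})
    if "secondary_composite" in results:
        _or_row(
            "Secondary: odds of prioritized patient having the highest composite "
            "outcome score greater in the intervention arm (site 1, pooled logistic)",
            results["secondary_composite"],
        )
    else:
        rows.append({"Hypothesis": "Secondary (composite)", "Result": "WARNING: block missing"})
    if "secondary_news_diff" in results:
        z = results["secondary_news_diff"]["pooled_z"]
        rows.append(
            {
                "Hypothesis": "Secondary: larger prioritized-vs-delayed NEWS difference "
                "in the intervention arm (pooled rank-sum)",
                "Result": f"Z = {z['point']:.3f}, p = {z['p_value']:.3f}",
            }
        )
    else:
        rows.append({"Hypothesis": "Secondary (NEWS diff)", "Result": "WARNING: block missing"})
    return pd.DataFrame(rows)


def ancillary_text(results: dict) -> str:
    lines = []
    comp = results.get("compliance")
    if comp:
        for key in ("control", "intervention", "confidence_high", "confidence_low"):
            if key in comp and "rate" in comp[key] and not np.isnan(comp[key]["rate"]):
                c = comp[key]
                lines.append(
                    f"model agreement, {key}: {100 * c['rate']:.1f}% "
                    f"(95% CI [{100 * c['ci_low']:.1f}, {100 * c['ci_high']:.1f}], n={c['n']})"
                )
    else:
        lines.append("WARNING: compliance block missing")
    for key, label in (
        ("full_compliance_counterfactual", "100% compliance counterfactual"),
        ("blended_counterfactual", "confidence-blended strategy"),
    ):
        blk = results.get(key)
        if blk:
            orr = blk["odds_ratio"]
            lines.append(
                f"{label}: accuracy {100 * blk['accuracy']:.1f}%, OR {orr['or']:.2f} "
                f"(95% CI [{orr['ci_low']:.2f}, {orr['ci_high']:.2f}])"
            )
    if "random_baseline_accuracy" in results:
        lines.append(
            f"random prioritization baseline: "
            f"{100 * results['random_baseline_accuracy']:.1f}%"
        )
    tt = results.get("time_trends")
    if tt:
        c = tt["intervention_compliance_trend"]
        lines.append(
            f"compliance trend (intervention): OR/month {c['slope_or_per_month']:.3f} "
            f"(95% CI [{c['ci_low']:.3f}, {c['ci_high']:.3f}], p = {c['p_value']:.3f})"
        )
        s = tt["control_accuracy_trend"]
        lines.append(
            f"spillover trend (control accuracy): OR/month {s['slope_or_per_month']:.3f} "
            f"(95% CI [{s['ci_low']:.3f}, {s['ci_high']:.3f}], p = {s['p_value']:.3f})"
        )
    dr = results.get("drift")
    if dr:
        lines.append(
            f"drift: Spearman slope/month since update {dr['slope_per_month']:.4f} "
            f"(95% CI [{dr['ci_low']:.4f}, {dr['ci_high']:.4f}], p = {dr['p_value']:.3f})"
        )
    cal = results.get("calibration")
    if cal is not None:
        sig = [t for t in cal["significant_terms"] if t.startswith("call_type_")]
        lines.append(
            f"calibration: residual age/sex terms significant: "
            f"{[t for t in cal['significant_terms'] if t in ('age', 'sex_male')]}; "
            f"{len(sig)} call-type indicator(s) significant"
        )
    return "\n".join(lines) + "\n"


def render_report(results: dict, sim=None, imp=None, seed: int = 0) -> dict:
    """Render all report artifacts; returns {name: DataFrame or text}."""
    out = {}
    if sim is not None:
        out["table1_cohort"] = cohort_table(sim, imp, seed=seed)
    out["table2_hypotheses"] = hypothesis_table(results)
    txt = out["table2_hypotheses"].to_string(index=False)
    out["report"] = (
        "Trial summary\n=============\n\n" + txt + "\n\nAncillary analyses\n"
        "------------------\n" + ancillary_text(results)
    )
    return out
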