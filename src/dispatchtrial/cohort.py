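"""Synthetic dispatch-trial cohort generator.

Emulates the structure of a randomized ambulance-dispatch prioritization
trial in a low-acuity adult cohort: patients arrive in resource-constrained
situations (RCS — more patients awaiting an ambulance than ambulances
available), each patient carries a single latent acuity scalar that drives
their vital signs, proxy outcomes, the risk model's predictions and the
dispatch nurse's perception, and vital-sign documentation is incomplete in
a configurable, mildly outcome-dependent (MAR) way.

Vital signs are generated by *ordinal band sampling*: for every NEWS 2
component the probability mass over the chart's scoring bands is shifted
by latent acuity through a proportional-odds model, and a concrete reading
is then drawn uniformly inside the sampled band.  This gives direct control
over the NEWS distribution (mean ~ 3 in this population) and guarantees a
monotone acuity -> NEWS association.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import GeneratorConfig
from .news import ACVPU_LEVELS, COMPONENTS

# --------------------------------------------------------------------------
# ordinal band model
#
# For each component: severity-ordered levels with (points, sampling range)
# and baseline tail probabilities P(level >= j) at acuity 0 (before the
# global intercept shift that calibrates the cohort NEWS mean).
# Where the chart has several bands worth the same points (e.g. brady- vs
# tachycardia) one clinically typical direction is generated; scoring still
# covers the full chart.

_BAND = {
    "respiratory_rate": {
        "points": (0, 1, 2, 3),
        "ranges": ((12, 20), (9, 11), (21, 24), (25, 35)),
        "tails": (0.20, 0.13, 0.05),
        "grid": "int",
    },
    "spo2": {
        "points": (0, 1, 2, 3),
        "ranges": ((96, 100), (94, 95), (92, 93), (85, 91)),
        "tails": (0.25, 0.13, 0.05),
        "grid": "int",
    },
    "on_oxygen": {
        "points": (0, 2),
        "ranges": (None, None),
        "tails": (0.10,),
        "grid": "bool",
    },
    "systolic_bp": {
        "points": (0, 1, 2, 3),
        "ranges": ((111, 180), (101, 110), (91, 100), (70, 90)),
        "tails": (0.22, 0.12, 0.04),
        "grid": "int",
    },
    "pulse": {
        "points": (0, 1, 2, 3),
        "ranges": ((51, 90), (91, 110), (111, 130), (131, 170)),
        "tails": (0.28, 0.11, 0.04),
        "grid": "int",
    },
    "consciousness": {
        "points": (0, 3),
        "ranges": (None, None),
        "tails": (0.07,),
        "grid": "acvpu",
    },
    "temperature": {
        "points": (0, 1, 2, 3),
        "ranges": ((36.1, 38.0), (38.1, 39.0), (39.1, 41.0), (33.0, 35.0)),
        "tails": (0.20, 0.08, 0.03),
        "grid": "temp",
    },
}

#: call-type complaint groups (41, frequency-ranked with a Zipf-like tail)
CALL_TYPES = (
    "general_elderly", "abdominal_pain", "difficulty_breathing", "fall",
    "weakness_fatigue", "infection_fever", "chest_pain", "nausea_vomiting",
    "dizziness", "back_pain", "urinary_complaint", "confusion",
    "extremity_pain", "headache", "minor_trauma", "palpitations",
    "syncope", "wound", "allergic_reaction", "psychiatric",
    "intoxication", "seizure_history", "diabetes_related", "bleeding_minor",
    "constipation", "catheter_problem", "rash", "eye_complaint",
    "ear_complaint", "dental", "joint_swelling", "hypertension_concern",
    "medication_issue", "post_operative", "oncology_related", "dialysis_related",
    "pregnancy_related", "social_concern", "device_alarm", "unspecified_pain",
    "other",
)

#: baseline logits of the four proxy outcomes (abnormal primary assessment;
#: lights-and-sirens transport; prehospital intervention; 72 h admission or
#: 30 d mortality) at acuity 0
PROXY_OUTCOMES = ("abnormal_assessment", "lights_sirens", "intervention", "admission_mortality")
_PROXY_BASE_LOGIT = {
    "abnormal_assessment": logit(0.35),
    "lights_sirens": logit(0.07),
    "intervention": logit(0.25),
    "admission_mortality": logit(0.40),
}
_PROXY_SLOPE = 1.0

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _thetas(shift: float) -> dict:
    return {
        c: np.array([logit(t) for t in spec["tails"]]) + shift
        for c, spec in _BAND.items()
    }


def _level_tails(a: np.ndarray, slope: float, shift: float) -> dict:
    """P(level >= j | acuity a) per component; a is an array."""
    th = _thetas(shift)
    return {c: expit(th[c][None, :] + slope * a[:, None]) for c in _BAND}


def expected_news(a, config: GeneratorConfig) -> np.ndarray:
    """Analytic E[NEWS | acuity] under the band model."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    tails = _level_tails(a, config.band_slope, _intercept_shift(config))
    out = np.zeros(len(a))
    for c, spec in _BAND.items():
        pts = np.asarray(spec["points"], dtype=float)
        dpts = np.diff(pts)  # increment in points when crossing tail j
        out += tails[c] @ dpts
    return out


def news_conditional_sd(a, config: GeneratorConfig) -> np.ndarray:
    """Analytic SD of NEWS given acuity (components independent given a)."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    tails = _level_tails(a, config.band_slope, _intercept_shift(config))
    var = np.zeros(len(a))
    for c, spec in _BAND.items():
        pts = np.asarray(spec["points"], dtype=float)
        T = tails[c]
        probs = np.diff(
            np.concatenate([np.ones((len(a), 1)), T, np.zeros((len(a), 1))], axis=1),
        ) * -1.0
        m1 = probs @ pts
        m2 = probs @ pts**2
        var += m2 - m1**2
    return np.sqrt(np.maximum(var, 1e-12))


def _population_mean_news(shift: float, slope: float, acuity_sd: float) -> float:
    a = _GH_NODES * acuity_sd
    tails = _level_tails(a, slope, shift)
    total = 0.0
    for c, spec in _BAND.items():
        dpts = np.diff(np.asarray(spec["points"], dtype=float))
        total += float(_GH_WEIGHTS @ (tails[c] @ dpts))
    return total


_SHIFT_CACHE: dict = {}


def _intercept_shift(config: GeneratorConfig) -> float:
    """Global band-intercept shift calibrating the cohort NEWS mean.

    Solved (bisection on the analytic population mean) so that the marginal
    mean NEWS over acuity ~ N(0, acuity_sd) equals ``baseline_news``.
    """
    key = (round(config.baseline_news, 6), round(config.band_slope, 6), round(config.acuity_sd, 6))
    if key not in _SHIFT_CACHE:
        lo, hi = -4.0, 4.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _population_mean_news(mid, config.band_slope, config.acuity_sd) < config.baseline_news:
                lo = mid
            else:
                hi = mid
        _SHIFT_CACHE[key] = 0.5 * (lo + hi)
    return _SHIFT_CACHE[key]


# --------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GeneratorConfig):
    """Generate the patient and RCS-membership tables.

    Returns ``(patients, rcs)``.  Each RCS draws its size from
    ``rcs_size_dist`` and additionally carries one *late-arrival* candidate
    patient (``late_arrival=True``) that the trial engine includes only when
    a repeat randomization grows the comparison; unused candidates are
    dropped by the pipeline.  Deterministic under a fixed seed.
    """
    rng = config.rng("cohort")
    sizes = np.array(sorted(config.rcs_size_dist), dtype=int)
    probs = np.array([config.rcs_size_dist[int(s)] for s in sizes], dtype=float)
    n = config.n_rcs
    rcs_sizes = rng.choice(sizes, size=n, p=probs)

    # arrival times: uniform over the study window, ordered
    month = np.sort(rng.integers(0, config.n_months, size=n))
    within = rng.uniform(0, 1, size=n)
    order = np.lexsort((within, month))
    month, within = month[order], within[order]
    site = np.where(
        (month >= config.site2_start_month) & (rng.uniform(size=n) < config.site2_prob), 2, 1
    )

    rcs = pd.DataFrame(
        {
            "rcs_id": [f"R{i:06d}" for i in range(n)],
            "size": rcs_sizes,
            "month": month,
            "time": month + within,
            "site": site,
        }
    )

    n_pat = int(rcs_sizes.sum()) + n  # one late-arrival candidate per RCS
    rcs_id = np.repeat(rcs.rcs_id.to_numpy(), rcs_sizes + 1)
    late = np.zeros(n_pat, dtype=bool)
    late[np.cumsum(rcs_sizes + 1) - 1] = True

    acuity = rng.normal(0.0, config.acuity_sd, size=n_pat)
    age = 18.0 + 82.0 * rng.beta(2.2, 1.05, size=n_pat)
    sex = np.where(rng.uniform(size=n_pat) < config.female_prob, "female", "male")
    ct_probs = 1.0 / np.arange(1, len(CALL_TYPES) + 1) ** 0.85
    ct_probs /= ct_probs.sum()
    call_type = rng.choice(CALL_TYPES, size=n_pat, p=ct_probs)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n_pat)],
            "rcs_id": rcs_id,
            "late_arrival": late,
            "age": np.round(age, 1),
            "sex": sex,
            "call_type": call_type,
            "latent_acuity": acuity,
        }
    )
    # proxy outcomes driven by the same latent scalar
    for name in PROXY_OUTCOMES:
        p = expit(_PROXY_BASE_LOGIT[name] + _PROXY_SLOPE * acuity)
        patients[name] = (rng.uniform(size=n_pat) < p).astype(int)
    return patients, rcs


def generate_vitals(patients: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Draw each patient's true first-assessment vitals from the band model."""
    rng = config.rng("vitals")
    a = patients["latent_acuity"].to_numpy()
    npat = len(a)
    tails = _level_tails(a, config.band_slope, _intercept_shift(config))
    out = pd.DataFrame({"patient_id": patients["patient_id"].to_numpy()})
    for comp, spec in _BAND.items():
        u = rng.uniform(size=npat)
        level = (u[:, None] < tails[comp]).sum(axis=1)
        grid = spec["grid"]
        if grid == "bool":
            out[comp] = level.astype(bool)
        elif grid == "acvpu":
            vals = np.full(npat, "Alert", dtype=object)
            nonalert = level > 0
            # mostly new confusion in an elderly low-acuity cohort
            vals[nonalert] = rng.choice(
                ACVPU_LEVELS[1:], size=int(nonalert.sum()), p=(0.70, 0.15, 0.10, 0.05)
            )
            out[comp] = vals
        else:
            ranges = spec["ranges"]
            vals = np.empty(npat)
            for lv, rg in enumerate(ranges):
                mask = level == lv
                if not mask.any():
                    continue
                lo, hi = rg
                if grid == "int":
                    vals[mask] = rng.integers(int(lo), int(hi) + 1, size=int(mask.sum()))
                else:  # temperature, 0.1 degC grid
                    k = int(round((hi - lo) * 10))
                    vals[mask] = lo + rng.integers(0, k + 1, size=int(mask.sum())) / 10.0
            out[comp] = np.round(vals, 1)
    return out


def apply_missingness(
    vitals: pd.DataFrame, patients: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Apply two-stage documentation missingness to a complete vitals table.

    Ambulance-stage missingness per component at ``miss_rate_ambulance``;
    hospital supplementation then restores enough entries to leave the
    ``miss_rate_final`` rates.  Unless ``mcar`` is set, the per-patient
    missingness odds are tilted by ``-miss_acuity_beta * latent_acuity``
    (sicker patients are more completely documented).  A ``src_<component>``
    column records ambulance / hospital / missing provenance.
    """
    merged = vitals.merge(
        patients[["patient_id", "latent_acuity"]], on="patient_id", validate="1:1"
    )
    a = merged["latent_acuity"].to_numpy()
    rng = config.rng("missingness")
    out = vitals.copy()
    for comp in COMPONENTS:
        p_amb = config.miss_rate_ambulance.get(comp, 0.0)
        p_fin = config.miss_rate_final.get(comp, 0.0)
        if p_amb == 0.0:
            out[f"src_{comp}"] = "ambulance"
            continue
        if config.mcar:
            pa = np.full(len(a), p_amb)
            pf = np.full(len(a), p_fin)
        else:
            tilt = -config.miss_acuity_beta * a
            pa = expit(logit(np.clip(p_amb, 1e-9, 1 - 1e-9)) + tilt)
            pf = expit(logit(np.clip(p_fin, 1e-9, 1 - 1e-9)) + tilt)
        amb_missing = rng.uniform(size=len(a)) < pa
        with np.errstate(divide="ignore", invalid="ignore"):
            keep_ratio = np.where(pa > 0, np.minimum(pf / np.maximum(pa, 1e-12), 1.0), 0.0)
        final_missing = amb_missing & (rng.uniform(size=len(a)) < keep_ratio)
        src = np.full(len(a), "ambulance", dtype=object)
        src[amb_missing] = "hospital"
        src[final_missing] = "missing"
        if out[comp].dtype == bool:
            out[comp] = out[comp].astype(object)
        out.loc[final_missing, comp] = np.nan if comp != "consciousness" else pd.NA
        out[f"src_{comp}"] = src
    return out


def assign_optouts(patients: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Flag patients who retroactively decline participation.

    Independent per-patient Bernoulli(``optout_prob_per_patient``); any RCS
    containing an opted-out patient is excluded downstream.
    """
    rng = config.rng("optout")
    out = patients.copy()
    out["optout"] = rng.uniform(size=len(out)) < config.optout_prob_per_patient
    return out
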