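"""NEWS 2 (National Early Warning Score, version 2) scoring.

The seven component items — respiratory rate, oxygen saturation (SpO2,
Scale 1), supplemental oxygen, systolic blood pressure, pulse rate, level
of consciousness (ACVPU) and temperature — each contribute 0–3 points; the
total ranges 0–20.  The banding chart is shipped as a human-readable CSV
(``data/news2_chart.csv``) which is the single source of truth: the scorer
does nothing but look values up in it, so tests can diff the table against
an independent transcription of the published chart.

Scale 2 (hypercapnic respiratory failure oxygen targets) is deliberately
unsupported: the data model carries no target-range flag.  "New confusion"
scores 3, the NEWS 2 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: canonical component order used throughout the package
COMPONENTS = (
    "respiratory_rate",
    "spo2",
    "on_oxygen",
    "systolic_bp",
    "pulse",
    "consciousness",
    "temperature",
)

NUMERIC_COMPONENTS = ("respiratory_rate", "spo2", "systolic_bp", "pulse", "temperature")

ACVPU_LEVELS = ("Alert", "Confusion", "Voice", "Pain", "Unresponsive")

#: admissible physiological ranges (validation, not scoring)
PHYSIOLOGICAL_RANGE = {
    "respiratory_rate": (0.0, 60.0),
    "spo2": (50.0, 100.0),
    "systolic_bp": (40.0, 300.0),
    "pulse": (20.0, 220.0),
    "temperature": (30.0, 43.0),
}

MAX_TOTAL = 20


class ScoringError(ValueError):
    """Unknown component, out-of-range value, or missing input."""


class MissingComponentError(ScoringError):
    """Raised when asked to score vitals with missing components.

    Scores must never be computed on incomplete rows; imputation has to
    run first and totals are then calculated from completed components.
    """


@dataclass(frozen=True)
class NewsScore:
    """A scored assessment: seven component points and their total."""

    component_points: dict
    total: int
    complete: bool = True

    def __post_init__(self):
        if self.total != sum(self.component_points.values()):
            raise ScoringError("total must equal the sum of component points")


def _load_chart() -> pd.DataFrame:
    with resources.files("dispatchtrial.data").joinpath("news2_chart.csv").open() as fh:
        chart = pd.read_csv(fh, comment="#", dtype={"category": "string"})
    return chart


_CHART = _load_chart()
# pre-split lookup tables
_RANGE_ROWS = {
    c: _CHART[(_CHART.component == c) & (_CHART.kind == "range")][["lo", "hi", "points"]]
    .astype(float)
    .to_numpy()
    for c in NUMERIC_COMPONENTS
}
_CATEGORY_ROWS = {
    (c, str(cat)): int(p)
    for c, cat, p in _CHART[_CHART.kind == "category"][
        ["component", "category", "points"]
    ].itertuples(index=False)
}


def chart() -> pd.DataFrame:
    """Return a copy of the banding chart as shipped."""
    return _CHART.copy()


def _snap(component: str, value: float) -> float:
    # integer grid for counts/pressures, 0.1 degC for temperature; this makes
    # scoring invariant to equivalent decimal representations of a reading
    if component == "temperature":
        return round(float(value), 1)
    return float(round(float(value)))


def score_component(name: str, value) -> int:
    """Score one component reading against the chart (0–3 points)."""
    if name in ("consciousness", "on_oxygen"):
        if name == "on_oxygen" and isinstance(value, (bool, np.bool_, int)):
            value = bool(value)
        key = (name, str(value))
        if key not in _CATEGORY_ROWS:
            raise ScoringError(f"unrecognized {name} value: {value!r}")
        return _CATEGORY_ROWS[key]
    if name not in _RANGE_ROWS:
        raise ScoringError(f"unknown component: {name!r}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise MissingComponentError(f"missing value for {name}")
    v = _snap(name, value)
    lo, hi = PHYSIOLOGICAL_RANGE[name]
    if not (lo <= v <= hi):
        raise ScoringError(f"{name}={value} outside physiological range [{lo}, {hi}]")
    rows = _RANGE_ROWS[name]
    eps = 1e-9
    for blo, bhi, pts in rows:
        if blo - eps <= v <= bhi + eps:
            return int(pts)
    raise ScoringError(f"{name}={value} matched no chart band")  # pragma: no cover


def compute_news(vitals) -> NewsScore:
    """Compute a full NEWS 2 score from one complete set of vitals.

    ``vitals`` is a mapping (or Series) with the seven component keys.
    Any missing component raises :class:`MissingComponentError`: totals are
    only ever calculated from fully observed or imputed components.
    """
    points = {}
    for comp in COMPONENTS:
        if comp not in vitals or vitals[comp] is None or (
            isinstance(vitals[comp], float) and np.isnan(vitals[comp])
        ):
            raise MissingComponentError(f"cannot score: {comp} is missing")
        points[comp] = score_component(comp, vitals[comp])
    return NewsScore(component_points=points, total=sum(points.values()))


def score_table(vitals: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a complete vitals table.

    Returns a frame with one ``pts_<component>`` column per component plus
    ``news_total``.  Raises :class:`MissingComponentError` on any NaN.
    """
    out = pd.DataFrame(index=vitals.index)
    for comp in NUMERIC_COMPONENTS:
        col = vitals[comp].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise MissingComponentError(f"{comp} contains missing values")
        if comp == "temperature":
            v = np.round(col, 1)
        else:
            v = np.round(col)
        lo, hi = PHYSIOLOGICAL_RANGE[comp]
        if (v < lo).any() or (v > hi).any():
            raise ScoringError(f"{comp} contains out-of-range values")
        pts = np.full(len(v), -1, dtype=int)
        for blo, bhi, p in _RANGE_ROWS[comp]:
            pts[(v >= blo - 1e-9) & (v <= bhi + 1e-9)] = int(p)
        out[f"pts_{comp}"] = pts
    oxy = vitals["on_oxygen"]
    if oxy.isna().any():
        raise MissingComponentError("on_oxygen contains missing values")
    out["pts_on_oxygen"] = np.where(oxy.astype(bool).to_numpy(), 2, 0)
    cons = vitals["consciousness"]
    if cons.isna().any():
        raise MissingComponentError("consciousness contains missing values")
    bad = ~cons.isin(ACVPU_LEVELS)
    if bad.any():
        raise ScoringError(f"invalid ACVPU levels: {sorted(cons[bad].unique())}")
    out["pts_consciousness"] = np.where(cons.to_numpy() == "Alert", 0, 3)
    out["news_total"] = out[[f"pts_{c}" for c in COMPONENTS]].sum(axis=1)
    return out


def rcs_winner_set(scores: dict) -> set:
    """Members of a resource-constrained situation achieving the maximum score.

    A prioritization is "correct" when the prioritized member is in this
    set, so ties on the score count as correct by construction.  The set is
    invariant under any strictly increasing transform of the scores.
    """
    if not scores:
        raise ScoringError("empty comparison: no members to rank")
    top = max(scores.values())
    return {k for k, v in scores.items() if v == top}
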