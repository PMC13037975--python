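"""Multiple imputation of NEWS components by chained equations.

Missing vital-sign components are imputed on their measurement scale and
only afterwards banded and summed into NEWS totals (scores are never
imputed directly).  Two chained-equation engines are provided:

``rf``
    Random-forest conditional draws (the default): each component is
    modeled by a small forest on the other components plus demographics,
    and every missing entry is filled with the observed value of a random
    donor from a random tree's leaf.  This mirrors the *rf* method of
    chained-equation imputation in common use.
``pmm``
    Predictive mean matching: a bootstrap OLS fit approximates a posterior
    parameter draw and each missing entry receives the observed value of
    one of the k = 5 donors with the nearest predicted mean.

Both engines impute by donor draws, so imputed values always lie within
the observed support (valid ACVPU levels, booleans, physiologic ranges).
Consciousness is carried as an ordinal A<C<V<P<U code during imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .news import ACVPU_LEVELS, COMPONENTS


class UnimputableError(ValueError):
    """A column has no observed values to learn from."""


class DiagnosticsError(ValueError):
    """Diagnostics need at least two chains and two iterations."""


_ACVPU_CODE = {lvl: i for i, lvl in enumerate(ACVPU_LEVELS)}


@dataclass
class ImputationSet:
    """m completed copies of a vitals table plus chain bookkeeping."""

    m: int
    tables: list
    seed: int
    iterations: int
    engine: str
    chain_stats: pd.DataFrame = field(repr=False, default=None)

    def long_table(self) -> pd.DataFrame:
        """All completed tables stacked with an imputation-index column."""
        parts = []
        for i, t in enumerate(self.tables, start=1):
            part = t.copy()
            part.insert(0, "imputation", i)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def _encode(vitals: pd.DataFrame, predictors: pd.DataFrame) -> tuple:
    df = vitals.merge(predictors, on="patient_id", validate="1:1")
    n = len(df)
    cols = list(COMPONENTS)
    X = np.empty((n, len(cols) + 2))
    for j, comp in enumerate(cols):
        if comp == "consciousness":
            X[:, j] = df[comp].map(_ACVPU_CODE).to_numpy(dtype=float, na_value=np.nan)
        elif comp == "on_oxygen":
            X[:, j] = df[comp].astype(float).to_numpy(na_value=np.nan)
        else:
            X[:, j] = df[comp].to_numpy(dtype=float, na_value=np.nan)
    X[:, len(cols)] = df["age"].to_numpy(dtype=float)
    X[:, len(cols) + 1] = (df["sex"].to_numpy() == "female").astype(float)
    return X, cols


def _decode(X: np.ndarray, cols: list, template: pd.DataFrame) -> pd.DataFrame:
    out = template.copy()
    for j, comp in enumerate(cols):
        if comp == "consciousness":
            out[comp] = [ACVPU_LEVELS[int(round(v))] for v in X[:, j]]
        elif comp == "on_oxygen":
            out[comp] = X[:, j] >= 0.5
        elif comp == "temperature":
            out[comp] = np.round(X[:, j], 1)
        else:
            out[comp] = np.round(X[:, j]).astype(int)
    return out


def _pmm_draw(Xo, yo, Xm, rng, k=5):
    Xo1 = np.column_stack([np.ones(len(Xo)), Xo])
    Xm1 = np.column_stack([np.ones(len(Xm)), Xm])
    beta_hat, *_ = np.linalg.lstsq(Xo1, yo, rcond=None)
    boot = rng.integers(0, len(yo), size=len(yo))
    beta_star, *_ = np.linalg.lstsq(Xo1[boot], yo[boot], rcond=None)
    d_obs = Xo1 @ beta_hat
    d_mis = Xm1 @ beta_star
    dist = np.abs(d_obs[None, :] - d_mis[:, None])
    kk = min(k, len(yo))
    nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    pick = nearest[np.arange(len(Xm)), rng.integers(0, kk, size=len(Xm))]
    return yo[pick]


def _rf_draw(Xo, yo, Xm, rng):
    n_trees = 10
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_depth=12,
        min_samples_leaf=5,
        n_jobs=1,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    forest.fit(Xo, yo)
    leaves_obs = forest.apply(Xo)  # (n_obs, n_trees)
    leaves_mis = forest.apply(Xm)
    tree_pick = rng.integers(0, n_trees, size=len(Xm))
    out = np.empty(len(Xm))
    for t in range(n_trees):
        rows = np.flatnonzero(tree_pick == t)
        if rows.size == 0:
            continue
        donors: dict = {}
        for i, leaf in enumerate(leaves_obs[:, t]):
            donors.setdefault(leaf, []).append(i)
        for i in rows:
            cand = donors.get(leaves_mis[i, t])
            if not cand:  # pragma: no cover - leaves always contain training rows
                cand = range(len(yo))
            out[i] = yo[int(rng.choice(cand))]
    return out


def impute_components(
    vitals: pd.DataFrame,
    predictors: pd.DataFrame,
    m: int = 10,
    iterations: int = 10,
    seed: int = 0,
    engine: str = "rf",
) -> ImputationSet:
    """Run m independent chained-equation chains on a vitals table.

    ``vitals`` holds the seven component columns (with NaN/NA for missing)
    plus ``patient_id``; ``predictors`` supplies ``age`` and ``sex``.
    Observed cells are never altered; with zero missing cells the result is
    m identical copies of the input.
    """
    X0, cols = _encode(vitals, predictors)
    comp_idx = {c: j for j, c in enumerate(cols)}
    miss = {c: np.isnan(X0[:, comp_idx[c]]) for c in cols}
    for c in cols:
        if miss[c].all():
            raise UnimputableError(f"component {c!r} has no observed values")

    any_missing = any(miss[c].any() for c in cols)
    template = vitals.copy()
    tables, stats = [], []
    root = np.random.SeedSequence(seed)
    for chain, ss in enumerate(root.spawn(m), start=1):
        rng = np.random.default_rng(ss)
        X = X0.copy()
        if not any_missing:
            tables.append(_decode(X, cols, template))
            continue
        # initialize missing cells by marginal draws from observed values
        for c in cols:
            mk = miss[c]
            if mk.any():
                obs = X0[~mk, comp_idx[c]]
                X[mk, comp_idx[c]] = rng.choice(obs, size=int(mk.sum()), replace=True)
        draw = _rf_draw if engine == "rf" else _pmm_draw
        for it in range(1, iterations + 1):
            for c in cols:
                mk = miss[c]
                if not mk.any():
                    continue
                j = comp_idx[c]
                others = [jj for jj in range(X.shape[1]) if jj != j]
                Xo, yo = X[~mk][:, others], X0[~mk, j]
                Xm = X[mk][:, others]
                X[mk, j] = draw(Xo, yo, Xm, rng)
                stats.append(
                    {
                        "chain": chain,
                        "iteration": it,
                        "component": c,
                        "mean_imputed": float(X[mk, j].mean()),
                        "var_imputed": float(X[mk, j].var()),
                    }
                )
        tables.append(_decode(X, cols, template))

    chain_stats = pd.DataFrame(stats) if stats else pd.DataFrame(
        columns=["chain", "iteration", "component", "mean_imputed", "var_imputed"]
    )
    return ImputationSet(
        m=m, tables=tables, seed=seed, iterations=iterations, engine=engine,
        chain_stats=chain_stats,
    )


@dataclass
class ImputationDiagnostics:
    """Chain-mixing summary for a chained-equation run."""

    table: pd.DataFrame  # per-component mixing ratio + flag
    threshold: float

    @property
    def flagged(self) -> list:
        return self.table.loc[self.table.flagged, "component"].tolist()


def diagnose(imp: ImputationSet, threshold: float = 1.2) -> ImputationDiagnostics:
    """Between/within-chain variance ratio per component (PSRF-style).

    Computed on the second half of each chain's mean-imputed-value
    trajectory; a ratio above ``threshold`` flags questionable mixing.
    Identical trajectories across chains give exactly 1.0.
    """
    st = imp.chain_stats
    if st is None or st.empty or st.chain.nunique() < 2 or st.iteration.nunique() < 2:
        raise DiagnosticsError("diagnostics require >= 2 chains and >= 2 iterations")
    rows = []
    for comp, grp in st.groupby("component"):
        half = grp[grp.iteration > grp.iteration.max() / 2]
        piv = half.pivot_table(index="iteration", columns="chain", values="mean_imputed")
        n_iter = len(piv)
        W = float(piv.var(axis=0, ddof=1).mean())
        B = float(piv.mean(axis=0).var(ddof=1)) * n_iter
        if W <= 1e-14:
            ratio = 1.0 if B <= 1e-14 else np.inf
        else:
            # PSRF clamped below at 1: identical chains give exactly 1.0
            psrf = float(np.sqrt(((n_iter - 1) / n_iter * W + B / n_iter) / W))
            ratio = max(1.0, psrf)
        rows.append({"component": comp, "within": W, "between": B, "ratio": ratio})
    table = pd.DataFrame(rows)
    table["flagged"] = table.ratio > threshold
    return ImputationDiagnostics(table=table, threshold=threshold)
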