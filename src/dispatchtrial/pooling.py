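"""Rubin's-rules combination of estimates across imputed datasets.

For m completed-data estimates Q_j with within variances U_j:

    Qbar = mean(Q_j)
    B    = var(Q_j)            (sample variance, ddof = 1)
    W    = mean(U_j)
    T    = W + (1 + 1/m) B

Degrees of freedom follow Barnard & Rubin's small-sample adjustment, with
the complete-data df supplied by the caller.  Rank-based tests are pooled
on the z scale: z-statistics are treated as estimates with unit within
variance, giving pooled z = mean(z) / sqrt(1 + (1 + 1/m) var(z)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class PooledEstimate:
    """A pooled point estimate with its variance decomposition."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    m: int
    flags: tuple = ()

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def barnard_rubin_df(m: int, between: float, total: float, df_complete: float) -> float:
    """Small-sample degrees of freedom for a Rubin-pooled estimate."""
    if m < 2:
        raise PoolingError("need m >= 2 imputations for pooled df")
    lam = (1.0 + 1.0 / m) * between / total if total > 0 else 0.0
    lam = min(max(lam, 0.0), 1.0 - 1e-12)
    if lam < 1e-12:
        return float(df_complete)
    nu_old = (m - 1) / lam**2
    nu_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
    return float(1.0 / (1.0 / nu_old + 1.0 / nu_obs))


def rubin_pool(points, within_vars, df_complete: float, alpha: float = 0.05,
               flags=()) -> PooledEstimate:
    """Pool m point estimates and their within-imputation variances."""
    q = np.asarray(points, dtype=float)
    u = np.asarray(within_vars, dtype=float)
    if q.ndim != 1 or q.shape != u.shape or q.size < 1:
        raise PoolingError("points and within_vars must be equal-length 1-D arrays")
    m = q.size
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b
    if m == 1 or b <= 1e-300:
        df = float(df_complete)
    else:
        df = barnard_rubin_df(m, b, t, df_complete)
    se = np.sqrt(t)
    if se > 0:
        tstat = qbar / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        lo, hi = qbar - tcrit * se, qbar + tcrit * se
    else:
        p, lo, hi = (0.0 if qbar != 0 else 1.0), qbar, qbar
    return PooledEstimate(
        point=qbar, within_var=w, between_var=b, total_var=t, df=df,
        p_value=float(p), ci_low=float(lo), ci_high=float(hi), m=m,
        flags=tuple(flags),
    )


def pool_z(z_values) -> PooledEstimate:
    """Pool per-imputation z-statistics (unit within variance)."""
    z = np.asarray(z_values, dtype=float)
    if z.size < 1 or np.isnan(z).any():
        raise PoolingError("z values must be present and finite for every imputation")
    m = z.size
    b = float(z.var(ddof=1)) if m > 1 else 0.0
    t = 1.0 + (1.0 + 1.0 / m) * b
    zpool = float(z.mean() / np.sqrt(t))
    p = 2.0 * stats.norm.sf(abs(zpool))
    return PooledEstimate(
        point=zpool, within_var=1.0, between_var=b, total_var=t,
        df=np.inf, p_value=float(p),
        ci_low=zpool - 1.959963984540054, ci_high=zpool + 1.959963984540054, m=m,
    )
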