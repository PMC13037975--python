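import numpy as np
import pandas as pd
import pytest

from dispatchtrial import GeneratorConfig, pipeline


def small_config(**over):
    """A quick-to-run configuration for unit tests."""
    defaults = dict(
        n_rcs=300, m_imputations=3, mice_iterations=4, mice_engine="pmm", seed=42
    )
    defaults.update(over)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulated trial."""
    cfg = small_config()
    return cfg, pipeline.simulate(cfg)


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Simulated trial + imputations + per-imputation outcome tables."""
    from dispatchtrial import analysis

    cfg, sim = small_sim
    imp = pipeline.impute(sim, cfg)
    ev = sim.analyzed_events
    prio = analysis.observed_prioritized(sim.dispatch)
    long_list = [analysis.member_news(t, ev) for t in imp.tables]
    outs = []
    for ln in long_list:
        o = analysis.build_rcs_outcomes(ln, ev, prio)
        o["arm_ind"] = (o.arm == "intervention").astype(int)
        outs.append(o)
    return cfg, sim, imp, long_list, outs


def complete_vitals_frame(n=50, seed=0):
    """A small complete vitals table with plausible values."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "respiratory_rate": rng.integers(10, 26, n),
            "spo2": rng.integers(90, 101, n),
            "on_oxygen": rng.uniform(size=n) < 0.1,
            "systolic_bp": rng.integers(95, 180, n),
            "pulse": rng.integers(55, 120, n),
            "consciousness": rng.choice(["Alert", "Confusion"], n, p=[0.92, 0.08]),
            "temperature": np.round(rng.uniform(35.5, 39.5, n), 1),
        }
    )
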