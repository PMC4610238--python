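import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tascore as tc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# fit-failure warnings on deliberately flat synthetic series are expected noise
logging.getLogger("tascore.dose_response").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_screen():
    """A modest synthetic screen shared by read-only tests (3 clusters, low noise)."""
    cfg = tc.SimulationConfig(
        seed=11,
        n_samples=12,
        n_compounds=16,
        n_targets=12,
        n_clusters=3,
        noise_sd=3.0,
    )
    series, truth, network = tc.simulate_screen(cfg)
    return cfg, series, truth, network


@pytest.fixture(scope="session")
def small_tas(small_screen):
    """AUC-metric TAS matrix of the small screen (no curve fitting needed)."""
    _, series, truth, network = small_screen
    responses = tc.build_response_matrix(series, "AUC")
    return tc.compute_tas(responses, network), truth, network


def tas_loop_oracle(dr: pd.DataFrame, compounds_of: dict[str, list[str]]) -> pd.DataFrame:
    """Independent per-target loop reference for the addiction score."""
    out = {}
    for t, comps in compounds_of.items():
        cols = [c for c in comps if c in dr.columns]
        if not cols:
            continue
        vals = []
        for s in dr.index:
            obs = [dr.at[s, c] for c in cols if pd.notna(dr.at[s, c])]
            vals.append(np.mean(obs) if obs else np.nan)
        out[t] = vals
    return pd.DataFrame(out, index=dr.index)
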