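"""Shared fixtures: one full-scale synthetic study reused across test modules."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import whistlegam as wg
from whistlegam.pipeline import global_model_spec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """Schedule, forcings, truth and hourly records at study scale (seed 1)."""
    return wg.simulate_study(seed=1)


@pytest.fixture(scope="session")
def study_frame(study):
    _, _, _, records = study
    return wg.records_to_frame(records)


@pytest.fixture(scope="session")
def study_fit(study_frame):
    """The fitted global GAM on the synthetic study (fitted once per session)."""
    spec = global_model_spec(
        study_frame, {"hour": 8, "moon": 8, "sst": 8, "depth": 4, "distance": 4, "tensor": 4}
    )
    return wg.fit(spec, study_frame)


@pytest.fixture(scope="session")
def clustered_frame(study_frame):
    """Study frame with the truth's seasonal cluster labels attached."""
    fr = study_frame.copy()
    fr["cluster"] = pd.to_datetime(fr["hour_start"]).map(wg.season_of)
    return fr


@pytest.fixture
def two_hour_window():
    return wg.DeploymentWindow(
        deployment_id="D1",
        station_id="S1",
        start=datetime(2018, 3, 1, 0, 0),
        end=datetime(2018, 3, 1, 2, 0),
    )


def redraw_counts(frame: pd.DataFrame, seed: int, cap: int = 6) -> pd.DataFrame:
    """Resample dp10m from the stored true log-rates (fast replicate draws)."""
    rng = np.random.default_rng(seed)
    out = frame.copy()
    lam = np.exp(out["true_log_rate"].to_numpy(float))
    n = rng.poisson(lam)
    out["dp10m"] = np.minimum(n, np.minimum(cap, out["n_bins_recorded"].to_numpy(int)))
    return out
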