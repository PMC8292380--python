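import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the LMM boundary warning and statsmodels convergence chatter are expected in
# simulation studies; keep test output readable
warnings.filterwarnings("ignore", message="random-intercept variance estimated")


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across test modules."""
    from socioepi.simulate import SimulationConfig, TrueEffects, simulate_dataset

    cfg = SimulationConfig(
        seed=42, n_mothers=18, offspring_per_mother=2, n_sessions=250,
        n_cpg=400, mean_coverage=30,
        effects=TrueEffects(frac_true_dms=0.05, beta_dms=1.2),
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_grouped_data(rng, n_groups=60, reps=3, beta=0.5, sigma_g=0.5, sigma_e=0.7):
    """Simple grouped regression dataset for LMM tests."""
    g = np.repeat([f"id{i:03d}" for i in range(n_groups)], reps)
    x = rng.standard_normal(n_groups * reps)
    u = rng.normal(0, sigma_g, n_groups)
    y = 1.0 + beta * x + np.repeat(u, reps) + rng.normal(0, sigma_e, n_groups * reps)
    return pd.DataFrame({"y": y, "x": x, "id": g})
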