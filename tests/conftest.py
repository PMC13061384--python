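import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bmr_table():
    from mixtox import datasets

    return datasets.load_benchmark_responses()


@pytest.fixture(scope="session")
def demo_truth():
    from mixtox.pipeline import demo_agent_truth

    return demo_agent_truth()


@pytest.fixture(scope="session")
def demo_screen(demo_truth):
    """One fixed-seed simulated single-agent screen (adult, day 12)."""
    from mixtox.pipeline import demo_design
    from mixtox.simulate import simulate_single_agent

    return simulate_single_agent(demo_truth, demo_design(seed=7), seed=7)


def make_activity_frame(concentrations, activities):
    """Small AChE-style activity table used across test modules."""
    return pd.DataFrame(
        {
            "condition": "X",
            "concentration_uM": np.asarray(concentrations, dtype=float),
            "replicate": 1,
            "percent_activity": np.asarray(activities, dtype=float),
        }
    )
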