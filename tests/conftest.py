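import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from undesired import synthdata


def small_sim_config(n_mothers: int = 500, seed: int = 0) -> synthdata.SimConfig:
    """A small-support configuration with exact enumerable prevalences."""
    sigma = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
    return synthdata.SimConfig(
        n_mothers=n_mothers,
        ideal_dist=[((2, 1, 1), 0.5), ((1, 1, 0), 0.3), ((0, 0, 2), 0.2)],
        births_dist=[(0, 0.1), (1, 0.2), (2, 0.3), (3, 0.2), (4, 0.1), (5, 0.1)],
        sex_ratio_male=0.512,
        u5_death_prob=0.08,
        covariate_spec={
            "edu": (["none", "primary", "secondary", "higher"], [0.5, 0.2, 0.2, 0.1]),
            "wealth": (["poor", "middle", "rich"], [0.45, 0.2, 0.35]),
            "resid": (["urban", "rural"], [0.47, 0.53]),
            "prov": (
                ["punjab", "sindh", "kpk", "balochistan", "ict", "fata"],
                [0.28, 0.2, 0.19, 0.12, 0.08, 0.13],
            ),
            "mage": (["<20", "20-29", "30-39", "40-49"], [0.09, 0.6, 0.29, 0.02]),
            "wsw": ([0, 1], [0.85, 0.15]),
            "exc_m": ([0, 1], [0.8, 0.2]),
            "empment": ([0, 1], [0.8, 0.2]),
            "visit_hw": ([0, 1], [0.45, 0.55]),
            "age_ch": ([0, 1, 2, 3, 4], [0.2, 0.2, 0.2, 0.2, 0.2]),
        },
        outcomes=["diarrhea", "fever", "cough"],
        outcome_beta={
            "diarrhea": {"intercept": -0.8, "bord": 0.05},
            "fever": {"intercept": -0.7, "age_ch": -0.05},
            "cough": {"intercept": -0.75},
        },
        outcome_sigma=sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_population():
    return synthdata.simulate_population(small_sim_config(500, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
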