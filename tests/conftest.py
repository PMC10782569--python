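import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy.optimize import brentq

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from prevdecomp.core import CovariateSpec
from prevdecomp.synthetic import ScenarioConfig, _marginal_prev, generate_frame


def make_two_wave_config() -> ScenarioConfig:
    """Small two-wave scenario with known effects and cluster variance."""
    edu = CovariateSpec(
        "education", ("low", "mid", "high"), reference="low", level="individual"
    )
    res = CovariateSpec("residence", ("urban", "rural"), reference="rural", level="community")
    return ScenarioConfig(
        waves=("w1", "w2"),
        strata=(("north", "urban"), ("north", "rural"), ("south", "urban"), ("south", "rural")),
        clusters_per_stratum=10,
        respondents_per_cluster=25,
        covariate_specs=(edu, res),
        composition={
            # residence is determined by the stratum, so it is constant
            # within every cluster — a genuine community-level covariate
            "w1": {
                "education": (0.6, 0.3, 0.1),
                "residence": {
                    "north|urban": (1.0, 0.0),
                    "south|urban": (1.0, 0.0),
                    "north|rural": (0.0, 1.0),
                    "south|rural": (0.0, 1.0),
                },
            },
            "w2": {
                "education": (0.4, 0.4, 0.2),
                "residence": {
                    "north|urban": (1.0, 0.0),
                    "south|urban": (1.0, 0.0),
                    "north|rural": (0.0, 1.0),
                    "south|rural": (0.0, 1.0),
                },
            },
        },
        fixed_effects={"education": {"mid": 0.8, "high": 1.5}, "residence": {"urban": 1.2}},
        intercept={"w1": -2.2, "w2": -1.4},
        cluster_sd=0.6,
        weight_model="inverse-selection",
        selection_prob={
            "north|urban": 0.9,
            "north|rural": 0.5,
            "south|urban": 0.8,
            "south|rural": 0.6,
        },
        seed=2024,
    )


@pytest.fixture(scope="session")
def two_wave_config() -> ScenarioConfig:
    return make_two_wave_config()


@pytest.fixture(scope="session")
def two_wave_frame(two_wave_config) -> pd.DataFrame:
    return generate_frame(two_wave_config)


def null_scenario(seed: int, sigma: float = 0.86, target_prev: float = 0.088) -> ScenarioConfig:
    """Single-wave, no-covariate scenario for variance recovery: ~300
    clusters of mean size 29 and a latent intercept solved so the marginal
    prevalence matches the target under the given cluster SD."""
    alpha = brentq(lambda a: float(_marginal_prev(np.array([a]), sigma)[0]) - target_prev, -8, 2)
    strata = tuple((f"r{i}", res) for i in range(3) for res in ("urban", "rural"))
    return ScenarioConfig(
        waves=("w1",),
        strata=strata,
        clusters_per_stratum=50,
        respondents_per_cluster=29,
        covariate_specs=(),
        composition={"w1": {}},
        fixed_effects={},
        intercept={"w1": alpha},
        cluster_sd=sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def toy_cluster_frame() -> pd.DataFrame:
    """3 clusters, 12 observations — small enough for brute-force
    integration of the marginal likelihood."""
    return pd.DataFrame(
        {
            "respondent_id": [str(i) for i in range(12)],
            "wave": "w",
            "stratum_id": "s",
            "cluster_id": np.repeat(["a", "b", "c"], 4),
            "weight": 1.0,
            "outcome": [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1],
            "x": ["u", "v", "u", "v"] * 3,
        }
    )
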