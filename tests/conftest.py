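import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from samloc import design, simulate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def localization_table():
    return design.build_localization_trials(seed=11)


@pytest.fixture(scope="session")
def paper_params():
    return simulate.paper_like_params()


@pytest.fixture(scope="session")
def one_cell_data():
    """One (delta_l=0, fm=120) condition at experiment scale: 48 doubles from
    the 24 speaker pairs (both target assignments) + 17 singles, simulated
    with known parameters g=1, b=0, sigma_s=8, w=0.5, sigma_d=10."""
    pairs = design.load_speaker_pairs()
    els = design.single_sound_elevations()
    T = np.r_[pairs.low_el.values, pairs.high_el.values].astype(float)
    D = np.r_[pairs.high_el.values, pairs.low_el.values].astype(float)
    rng = np.random.default_rng(42)
    truth = dict(g=1.0, b=0.0, sigma_s=8.0, w=0.5, sigma_d=10.0)
    singles = pd.DataFrame(
        {"target_el": els, "response_el": rng.normal(truth["g"] * els, truth["sigma_s"])}
    )
    mu = truth["g"] * (truth["w"] * T + (1 - truth["w"]) * D) + truth["b"]
    doubles = pd.DataFrame(
        {
            "target_el": T,
            "distractor_el": D,
            "delta_l_db": 0.0,
            "fm_hz": 120.0,
            "response_el": rng.normal(mu, truth["sigma_d"]),
        }
    )
    return singles, doubles, truth
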