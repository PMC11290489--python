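import numpy as np
import pandas as pd
import pytest

from rampscreen.calling import pair_scores
from rampscreen.io import build_score_input
from rampscreen.simulate import SimulationConfig, simulate_screen, simulate_truth_set


@pytest.fixture(scope="session")
def small_screen():
    """A 20-receptor screen with the default effect size, shared read-only."""
    cfg = SimulationConfig(n_gpcrs=20, seed=123)
    mfi, panel, sheet, truth = simulate_screen(cfg)
    return dict(config=cfg, mfi=mfi, panel=panel, sheet=sheet, truth=truth)


@pytest.fixture(scope="session")
def small_scored(small_screen):
    pairs, buffer = build_score_input(
        small_screen["mfi"], small_screen["panel"], small_screen["sheet"]
    )
    scored = pair_scores(pairs)
    return dict(scored=scored, buffer=buffer, **small_screen)


@pytest.fixture(scope="session")
def small_truth_set(small_screen):
    return simulate_truth_set(small_screen["truth"], coverage=1.0, label_noise=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_calls(rows):
    """Minimal call-matrix DataFrame from (gpcr, ramp, scheme, family, antibody, hit) tuples."""
    return pd.DataFrame(
        rows,
        columns=["gpcr_id", "ramp_id", "scheme_id", "capture_family", "capture_antibody_id", "hit"],
    )
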