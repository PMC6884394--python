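import numpy as np
import pandas as pd
import pytest

from rulemvpa import design, glm, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_atlas():
    """ROI-only phantom for fast end-to-end tests."""
    return synthetic.make_phantom_atlas(
        (16, 16, 16),
        {"vlpfc_signal": 48, "dlpfc_null": 16, "visual": 32, "motor": 32,
         "white_matter": 32, "striatum": 32},
        searchlight_radius=None,
    )


@pytest.fixture(scope="session")
def micro_design_exp1():
    """One-run exp1-style micro design (2 blocks per condition)."""
    return design.generate_experiment_design(
        "exp1", 123, n_runs=1, blocks_per_condition=2
    )


def isolated_trial_events(n_trials=8, spacing_s=40.0, n_stimuli=4, start_s=5.0):
    """Implementation-only events with non-overlapping HRF responses."""
    onsets = start_s + np.arange(n_trials) * spacing_s
    stimuli = list(range(n_stimuli)) * (n_trials // n_stimuli)
    reps = np.repeat(np.arange(1, n_trials // n_stimuli + 1), n_stimuli)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": 1.0,
            "run": 0,
            "block": 0,
            "condition": "easy",
            "phase": "implementation",
            "stimulus_id": stimuli,
            "repetition": reps,
            "stage": (reps + 1) // 2,
            "instructed_response": 0,
        }
    )


@pytest.fixture
def isolated_events():
    return isolated_trial_events()
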