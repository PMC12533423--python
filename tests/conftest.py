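import numpy as np
import pandas as pd
import pytest

from disfluency.io_preprocess import TRIAL_COLUMNS


def make_trials(rows):
    """Build a trial frame from (subject, item, rt, accuracy, ...) dicts with defaults."""
    defaults = {
        "subject_id": "s0", "item_id": "i0", "list_id": 1, "phase": "encoding",
        "task": "ldt", "blur": "clear", "frequency": "none",
        "stim_class": "word", "status": "na", "rt": 0.6,
        "response": "word", "accuracy": 1,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=TRIAL_COLUMNS)


@pytest.fixture
def toy_rts_trials():
    rts = [0.1, 0.19, 0.2, 0.5, 0.8, 1.0, 1.5, 2.5, 2.51, 3.0]
    return make_trials([{"item_id": f"i{k}", "rt": r} for k, r in enumerate(rts)])


@pytest.fixture
def small_exp1a():
    """A small Experiment-1A style synthetic dataset shared across tests."""
    from disfluency.synthetic import simulate_full_experiment

    trials, truth = simulate_full_experiment("1A", n_subjects=36, n_words=18, seed=11)
    return trials, truth
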