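import numpy as np
import pandas as pd
import pytest

from pavbias import HierarchicalGNG
from pavbias.cohort import GenerationConfig, generate_cohort


def trials_frame(records):
    """Long-format DataFrame from a list of TrialRecord."""
    return pd.DataFrame(
        {
            "subject": [t.subject for t in records],
            "session": [t.session for t in records],
            "trial": [t.trial for t in records],
            "condition": [t.condition.token for t in records],
            "response": ["go" if t.response else "nogo" for t in records],
            "outcome": [t.outcome for t in records],
        }
    )


def quit_groups(cohort: pd.DataFrame) -> dict:
    return {
        s: ("quit" if q else "nonquit") for s, q in zip(cohort["subject"], cohort["quit"])
    }


@pytest.fixture(scope="session")
def cohort15():
    """15-subject synthetic cohort (8 quitters / 7 non-quitters)."""
    return generate_cohort(GenerationConfig(n_quit=8, n_nonquit=7, seed=3))


@pytest.fixture(scope="session")
def fit15(cohort15):
    """Joint group fit of the 15-subject cohort at reduced sampler settings."""
    model = HierarchicalGNG(cohort15.trials, groups=quit_groups(cohort15.cohort))
    return model.fit(chains=2, iterations=600, warmup=300, seed=1)


@pytest.fixture(scope="session")
def cohort50():
    """50-subject cohort (25/25) for parameter recovery."""
    return generate_cohort(GenerationConfig(n_quit=25, n_nonquit=25, seed=11))


@pytest.fixture(scope="session")
def fit50(cohort50):
    model = HierarchicalGNG(cohort50.trials, groups=quit_groups(cohort50.cohort))
    return model.fit(chains=2, iterations=600, warmup=300, seed=5)
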