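import numpy as np
import pandas as pd
import pytest

from attnspike.spike_io import epoch_rates, filter_trials
from attnspike.synthetic import GroundTruthUnit, TaskConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One session, 3 units with planted attention/drug/gain-variance effects."""
    task = TaskConfig(trials_per_condition=20)
    units = [
        GroundTruthUnit(
            "att_drug", 12.0, attention_effect=1.5, drug_gain=0.75,
            gain_variance=0.15, predim_attend_gain=1.4, p2t_us=380.0,
        ),
        GroundTruthUnit(
            "flat", 10.0, attention_effect=1.0, drug_gain=1.0,
            gain_variance=0.0, p2t_us=170.0, cell_class="narrow",
        ),
        GroundTruthUnit(
            "att_only", 8.0, attention_effect=1.6, drug_gain=1.0,
            gain_variance=0.1, predim_attend_gain=1.5, p2t_us=420.0,
        ),
    ]
    return generate_session(task, units, seed=1234)


@pytest.fixture(scope="session")
def small_rates(small_session):
    trials = filter_trials(small_session.trials)
    return epoch_rates(small_session.spikes, trials)
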