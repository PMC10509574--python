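import numpy as np
import pytest

from pavbias.task import SessionData, TrialRecord, generate_schedule, simulate_agent
from pavbias.models import MODEL_LADDER, ParameterSet


def build_session(rows, subject_id="sub", session=1):
    """Session from (condition, response, outcome[, target_side]) tuples."""
    trials = []
    for i, row in enumerate(rows):
        cond, response, outcome = row[:3]
        side = row[3] if len(row) > 3 else "left"
        trials.append(TrialRecord(
            subject_id=subject_id, session=session, block=1 + i // 40,
            trial_index=i, condition=cond, target_side=side,
            response=response, outcome=outcome))
    return SessionData(subject_id=subject_id, session=session, trials=trials)


@pytest.fixture(scope="session")
def winning_spec():
    return MODEL_LADDER[-1]


@pytest.fixture(scope="session")
def winning_params(winning_spec):
    return ParameterSet(winning_spec, {
        "alpha": 0.2, "rho_rew": 4.0, "rho_pun": 4.0, "xi": 0.1,
        "b": 0.4, "pi": 0.8})


@pytest.fixture(scope="session")
def simulated_session(winning_spec, winning_params):
    """One 120-trial session simulated from the winning model."""
    rng = np.random.default_rng(42)
    schedule = generate_schedule(3, 10, rng)
    return simulate_agent(winning_spec, winning_params, schedule, rng)
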