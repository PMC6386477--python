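from datetime import date

import pytest

from trialkit import SimConfig, Trial, run_simulation, small_config
from trialkit.core import Participant, ParticipantState, Sex


@pytest.fixture(scope="session")
def small_result():
    """One scaled-down simulated trial shared by read-only tests."""
    return run_simulation(small_config(seed=11))


@pytest.fixture()
def participant():
    return Participant(
        participant_id="P001",
        sex=Sex.FEMALE,
        birth_date=date(1958, 6, 15),
        consent_date=date(2016, 3, 1),
    )


def make_participant(pid="P001", sex=Sex.FEMALE, state=ParticipantState.REGISTERED, **kw):
    p = Participant(
        participant_id=pid,
        sex=sex,
        birth_date=kw.pop("birth_date", date(1958, 6, 15)),
        consent_date=kw.pop("consent_date", date(2016, 3, 1)),
        **kw,
    )
    p.state = state
    return p
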