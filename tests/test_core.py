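"""Eligibility screening and the participant state machine."""

from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from trialkit.core import (
    ACTIVE_STATES,
    AuditLog,
    BaselineMeasures,
    DoseLevel,
    ParticipantState,
    Role,
    Sex,
    TERMINAL_STATES,
    TRANSITIONS,
    TrialEvent,
    check_exclusions,
    count_metabolic_criteria,
    is_eligible,
    replay_states,
    set_dose,
    transition,
)
from trialkit.errors import AuthorizationError, StateError, ValidationError

from conftest import make_participant

D = date(2016, 5, 1)


def measures(**kw):
    base = dict(
        waist_cm=70,
        glycemia_mg_dl=90,
        triglycerides_mg_dl=100,
        hdl_mg_dl=60,
        systolic_mmHg=110,
        diastolic_mmHg=70,
        creatinine_umol_l=80,
    )
    base.update(kw)
    return BaselineMeasures(**base)


class TestMetabolicCriteria:
    @pytest.mark.parametrize(
        "sex,kw,expected",
        [
            # three disorders: waist, glycemia, triglycerides
            (Sex.FEMALE, dict(waist_cm=90, glycemia_mg_dl=105, triglycerides_mg_dl=160,
                              hdl_mg_dl=55, systolic_mmHg=120, diastolic_mmHg=80), 3),
            # every value strictly below its cut-off
            (Sex.MALE, dict(waist_cm=99, glycemia_mg_dl=99, triglycerides_mg_dl=149,
                            hdl_mg_dl=41, systolic_mmHg=129, diastolic_mmHg=84), 0),
            # boundary values are inclusive ("or more" / "or less")
            (Sex.FEMALE, dict(waist_cm=85, glycemia_mg_dl=100, triglycerides_mg_dl=150,
                              hdl_mg_dl=50, systolic_mmHg=130, diastolic_mmHg=85), 5),
            # male waist threshold is 100, not 85
            (Sex.MALE, dict(waist_cm=85, glycemia_mg_dl=100, triglycerides_mg_dl=150,
                            hdl_mg_dl=40, systolic_mmHg=130, diastolic_mmHg=85), 4),
            # treatment flags substitute for the lab values
            (Sex.FEMALE, dict(on_tg_treatment=True, on_chol_treatment=True,
                              on_bp_treatment=True), 3),
            # diastolic alone satisfies the blood-pressure criterion
            (Sex.FEMALE, dict(diastolic_mmHg=85), 1),
        ],
    )
    def test_counts(self, sex, kw, expected):
        assert count_metabolic_criteria(measures(**kw), sex) == expected

    def test_missing_field_names_the_field(self):
        m = measures()
        m.hdl_mg_dl = None
        with pytest.raises(ValidationError, match="hdl_mg_dl"):
            count_metabolic_criteria(m, Sex.FEMALE)

    @given(
        waist=st.floats(50, 130),
        gly=st.floats(60, 125),
        tg=st.floats(50, 400),
        hdl=st.floats(20, 90),
        sys_=st.floats(90, 190),
        dia=st.floats(50, 120),
        sex=st.sampled_from([Sex.MALE, Sex.FEMALE]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_each_criterion(self, waist, gly, tg, hdl, sys_, dia, sex):
        """Turning any one disorder on never lowers the criteria count."""
        m = measures(waist_cm=waist, glycemia_mg_dl=gly, triglycerides_mg_dl=tg,
                     hdl_mg_dl=hdl, systolic_mmHg=sys_, diastolic_mmHg=dia)
        base = count_metabolic_criteria(m, sex)
        for kw in (
            dict(waist_cm=150), dict(glycemia_mg_dl=200), dict(on_tg_treatment=True),
            dict(on_chol_treatment=True), dict(on_bp_treatment=True),
        ):
            fields = dict(waist_cm=waist, glycemia_mg_dl=gly, triglycerides_mg_dl=tg,
                          hdl_mg_dl=hdl, systolic_mmHg=sys_, diastolic_mmHg=dia)
            fields.update(kw)
            assert count_metabolic_criteria(measures(**fields), sex) >= base

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError, match="glycemia"):
            measures(glycemia_mg_dl=-1)


class TestExclusions:
    def test_creatinine_strictly_above_cutoff(self):
        assert check_exclusions(measures(creatinine_umol_l=125)) == ["creatinine"]
        assert check_exclusions(measures(creatinine_umol_l=124)) == []

    def test_hyperglycemia_needs_two_high_samples(self):
        assert check_exclusions(measures(glycemia_mg_dl=130, repeat_glycemia_mg_dl=120)) == []
        assert check_exclusions(
            measures(glycemia_mg_dl=130, repeat_glycemia_mg_dl=128)
        ) == ["glycemia"]
        # one high sample without a confirming repeat does not exclude
        assert check_exclusions(measures(glycemia_mg_dl=130)) == []

    def test_all_clear(self):
        assert check_exclusions(measures()) == []

    def test_every_flag_reported(self):
        m = measures(on_metformin=True, recent_cancer=True, proteinuria=True,
                     on_excluded_drugs=True, excess_alcohol=True, creatinine_umol_l=200,
                     glycemia_mg_dl=130, repeat_glycemia_mg_dl=130)
        assert set(check_exclusions(m)) == {
            "glycemia", "metformin", "cancer", "creatinine",
            "proteinuria", "concomitant_drugs", "alcohol",
        }

    def test_eligibility_combines_both_rules(self):
        ok = measures(waist_cm=90, glycemia_mg_dl=105, triglycerides_mg_dl=160)
        assert is_eligible(ok, Sex.FEMALE)
        assert not is_eligible(measures(), Sex.FEMALE)  # no syndrome
        bad = measures(waist_cm=90, glycemia_mg_dl=105, triglycerides_mg_dl=160,
                       proteinuria=True)
        assert not is_eligible(bad, Sex.FEMALE)


class TestStateMachine:
    def test_table_closure(self):
        """Exactly the declared pairs are legal; everything else raises."""
        for state in ParticipantState:
            for event in TrialEvent:
                p = make_participant(state=state)
                if (state, event) in TRANSITIONS:
                    transition(p, event, D)
                    assert p.state == TRANSITIONS[(state, event)]
                else:
                    with pytest.raises(StateError):
                        transition(p, event, D)

    def test_terminal_states_accept_nothing(self):
        for state in TERMINAL_STATES:
            for event in TrialEvent:
                assert (state, event) not in TRANSITIONS

    def test_blocking_and_withdrawal_reachable_from_every_active_state(self):
        for state in ACTIVE_STATES:
            assert TRANSITIONS[(state, TrialEvent.NON_COMPLIANCE)] is ParticipantState.BLOCKED
            assert (
                TRANSITIONS[(state, TrialEvent.SERIOUS_ADVERSE_EVENT)]
                is ParticipantState.BLOCKED
            )
            assert (
                TRANSITIONS[(state, TrialEvent.CONSENT_WITHDRAWAL)]
                is ParticipantState.WITHDRAWN
            )

    def test_run_in_adverse_event_screen_fails(self):
        p = make_participant(state=ParticipantState.RUN_IN)
        transition(p, TrialEvent.RUN_IN_ADVERSE_EVENT, D)
        assert p.state is ParticipantState.SCREEN_FAILED

    def test_withdrawal_from_maintenance(self):
        p = make_participant(state=ParticipantState.MAINTENANCE)
        transition(p, TrialEvent.CONSENT_WITHDRAWAL, D)
        assert p.state is ParticipantState.WITHDRAWN
        with pytest.raises(StateError, match="WITHDRAWN"):
            transition(p, TrialEvent.MAINTENANCE_SUPPLY, D)

    def test_audit_replay_round_trip(self):
        """Replaying the audit log reconstructs every final state."""
        import random

        rng = random.Random(7)
        log = AuditLog()
        finals = {}
        for i in range(60):
            pid = f"P{i:03d}"
            p = make_participant(pid=pid)
            log.record("registration", pid, timestamp=D)
            for _ in range(rng.randrange(0, 10)):
                legal = [e for (s, e) in TRANSITIONS if s is p.state]
                if not legal:
                    break
                transition(p, rng.choice(legal), D, log)
            finals[pid] = p.state
        assert replay_states(log) == finals

    def test_audit_log_jsonl_round_trip(self):
        log = AuditLog()
        p = make_participant(state=ParticipantState.RUN_IN)
        transition(p, TrialEvent.TREATMENT_RANDOMIZATION, D, log, label="X")
        text = log.to_jsonl()
        back = AuditLog.from_jsonl(text)
        assert back.to_jsonl() == text
        assert back.events[0].payload["to"] == "TREATMENT_RANDOMIZED"


class TestSetDose:
    def test_pi_can_halve_and_it_is_idempotent(self):
        p = make_participant(state=ParticipantState.MAINTENANCE)
        set_dose(p, DoseLevel.HALF, actor_id="dr", actor_role=Role.PI, when=D)
        assert p.dose_level is DoseLevel.HALF
        set_dose(p, DoseLevel.HALF, actor_id="dr", actor_role=Role.PI, when=D)
        assert p.dose_level is DoseLevel.HALF

    def test_non_pi_rejected(self):
        p = make_participant(state=ParticipantState.MAINTENANCE)
        with pytest.raises(AuthorizationError):
            set_dose(p, DoseLevel.HALF, actor_id="dm", actor_role=Role.DATA_MANAGER, when=D)

    def test_before_randomization_rejected(self):
        p = make_participant(state=ParticipantState.RUN_IN)
        with pytest.raises(StateError):
            set_dose(p, DoseLevel.HALF, actor_id="dr", actor_role=Role.PI, when=D)
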