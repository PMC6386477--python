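"""Domain types, eligibility screening and the participant state machine.

Every participant is a *state*: the protocol flow (registration, diet
randomization, screening, a 30-day open-label run-in, treatment
randomization and the successive supply steps) is encoded as an explicit
transition table, and every transition appends exactly one event to an
append-only audit log.  All other modules are gated by the state held here.

Eligibility implements the metabolic-syndrome entry rule (at least three of
five disorders, with the printed thresholds inclusive) and the exclusion
rules (confirmed hyperglycemia on two samples, concomitant metformin, recent
cancer, renal impairment, proteinuria, excluded co-medication, excess
alcohol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date
from enum import Enum
from typing import Iterable, Optional

from .errors import AuthorizationError, StateError, ValidationError


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class DietArm(str, Enum):
    """Blue = active lifestyle intervention, green = control."""

    BLUE = "blue"
    GREEN = "green"


class DoseLevel(str, Enum):
    FULL = "full"
    HALF = "half"


class Role(str, Enum):
    DATA_MANAGER = "data_manager"
    PI = "PI"
    ADMINISTRATOR = "administrator"
    PHARMACIST = "pharmacist"


class ParticipantState(str, Enum):
    REGISTERED = "REGISTERED"
    DIET_RANDOMIZED = "DIET_RANDOMIZED"
    RUN_IN = "RUN_IN"
    SCREEN_FAILED = "SCREEN_FAILED"
    TREATMENT_RANDOMIZED = "TREATMENT_RANDOMIZED"
    SUPPLY_STEP_1 = "SUPPLY_STEP_1"
    SUPPLY_STEP_2 = "SUPPLY_STEP_2"
    MAINTENANCE = "MAINTENANCE"
    BLOCKED = "BLOCKED"
    WITHDRAWN = "WITHDRAWN"
    COMPLETED = "COMPLETED"


class TrialEvent(str, Enum):
    DIET_RANDOMIZATION = "diet_randomization"
    SCREENING_PASSED = "screening_passed"
    SCREEN_FAILURE = "screen_failure"
    RUN_IN_ADVERSE_EVENT = "run_in_adverse_event"
    TREATMENT_RANDOMIZATION = "treatment_randomization"
    FIRST_SUPPLY = "first_supply"
    SECOND_SUPPLY = "second_supply"
    MAINTENANCE_SUPPLY = "maintenance_supply"
    COMPLETION = "completion"
    NON_COMPLIANCE = "non_compliance"
    SERIOUS_ADVERSE_EVENT = "serious_adverse_event"
    CONSENT_WITHDRAWAL = "consent_withdrawal"


#: States from which a participant can still progress or be stopped.
ACTIVE_STATES = frozenset(
    {
        ParticipantState.REGISTERED,
        ParticipantState.DIET_RANDOMIZED,
        ParticipantState.RUN_IN,
        ParticipantState.TREATMENT_RANDOMIZED,
        ParticipantState.SUPPLY_STEP_1,
        ParticipantState.SUPPLY_STEP_2,
        ParticipantState.MAINTENANCE,
    }
)

#: States in which a participant is past treatment randomization and blinded.
RANDOMIZED_STATES = frozenset(
    {
        ParticipantState.TREATMENT_RANDOMIZED,
        ParticipantState.SUPPLY_STEP_1,
        ParticipantState.SUPPLY_STEP_2,
        ParticipantState.MAINTENANCE,
    }
)

TERMINAL_STATES = frozenset(
    {
        ParticipantState.SCREEN_FAILED,
        ParticipantState.WITHDRAWN,
        ParticipantState.COMPLETED,
    }
)


def _build_transition_table() -> dict:
    t = {
        (ParticipantState.REGISTERED, TrialEvent.DIET_RANDOMIZATION): ParticipantState.DIET_RANDOMIZED,
        (ParticipantState.DIET_RANDOMIZED, TrialEvent.SCREENING_PASSED): ParticipantState.RUN_IN,
        (ParticipantState.DIET_RANDOMIZED, TrialEvent.SCREEN_FAILURE): ParticipantState.SCREEN_FAILED,
        (ParticipantState.RUN_IN, TrialEvent.RUN_IN_ADVERSE_EVENT): ParticipantState.SCREEN_FAILED,
        (ParticipantState.RUN_IN, TrialEvent.TREATMENT_RANDOMIZATION): ParticipantState.TREATMENT_RANDOMIZED,
        (ParticipantState.TREATMENT_RANDOMIZED, TrialEvent.FIRST_SUPPLY): ParticipantState.SUPPLY_STEP_1,
        (ParticipantState.SUPPLY_STEP_1, TrialEvent.SECOND_SUPPLY): ParticipantState.SUPPLY_STEP_2,
        (ParticipantState.SUPPLY_STEP_2, TrialEvent.MAINTENANCE_SUPPLY): ParticipantState.MAINTENANCE,
        (ParticipantState.MAINTENANCE, TrialEvent.MAINTENANCE_SUPPLY): ParticipantState.MAINTENANCE,
        (ParticipantState.MAINTENANCE, TrialEvent.COMPLETION): ParticipantState.COMPLETED,
        # A blocked participant may still withdraw consent.
        (ParticipantState.BLOCKED, TrialEvent.CONSENT_WITHDRAWAL): ParticipantState.WITHDRAWN,
    }
    # Blocking and withdrawal are reachable from every active state.
    for s in ACTIVE_STATES:
        t[(s, TrialEvent.NON_COMPLIANCE)] = ParticipantState.BLOCKED
        t[(s, TrialEvent.SERIOUS_ADVERSE_EVENT)] = ParticipantState.BLOCKED
        t[(s, TrialEvent.CONSENT_WITHDRAWAL)] = ParticipantState.WITHDRAWN
    return t


#: The protocol flow.  (state, event) -> next state; anything else is illegal.
TRANSITIONS = _build_transition_table()


@dataclass
class Participant:
    """One enrolled volunteer.

    ``family_id`` links co-enrolled family members; the first member enrolled
    is the proband and later members are familiars, constrained to the
    proband's diet arm.  ``treatment_label`` is the blinded alias (X/Y),
    never a drug name.
    """

    participant_id: str
    sex: Sex
    birth_date: date
    consent_date: date
    family_id: Optional[str] = None
    is_proband: bool = True
    state: ParticipantState = ParticipantState.REGISTERED
    diet_arm: Optional[DietArm] = None
    treatment_label: Optional[str] = None
    dose_level: DoseLevel = DoseLevel.FULL
    anniversary_date: Optional[date] = None
    randomization_date: Optional[date] = None
    treatment_end_date: Optional[date] = None

    def age_at(self, when: date) -> int:
        """Age in whole years (floor) on ``when``."""
        years = when.year - self.birth_date.year
        if (when.month, when.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


@dataclass
class BaselineMeasures:
    """Baseline anthropometric and laboratory values used by screening.

    Treatment and history flags are pre-computed booleans from intake; the
    optional ``repeat_glycemia_mg_dl`` is the second fasting sample required
    to confirm the hyperglycemia exclusion.
    """

    waist_cm: Optional[float] = None
    glycemia_mg_dl: Optional[float] = None
    triglycerides_mg_dl: Optional[float] = None
    on_tg_treatment: bool = False
    hdl_mg_dl: Optional[float] = None
    on_chol_treatment: bool = False
    systolic_mmHg: Optional[float] = None
    diastolic_mmHg: Optional[float] = None
    on_bp_treatment: bool = False
    repeat_glycemia_mg_dl: Optional[float] = None
    creatinine_umol_l: Optional[float] = None
    proteinuria: bool = False
    on_metformin: bool = False
    recent_cancer: bool = False
    on_excluded_drugs: bool = False
    excess_alcohol: bool = False

    def __post_init__(self) -> None:
        for name in (
            "waist_cm",
            "glycemia_mg_dl",
            "triglycerides_mg_dl",
            "hdl_mg_dl",
            "repeat_glycemia_mg_dl",
            "creatinine_umol_l",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class AuditEvent:
    """One append-only audit record (who, when, what, about whom)."""

    timestamp: str
    actor_id: str
    actor_role: Role
    action: str
    subject: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["actor_role"] = self.actor_role.value
        return json.dumps(d, sort_keys=True)


class AuditLog:
    """Append-only event log; the single source of truth for replay."""

    def __init__(self, events: Optional[Iterable[AuditEvent]] = None) -> None:
        self._events: list[AuditEvent] = list(events or [])

    def append(self, event: AuditEvent) -> AuditEvent:
        self._events.append(event)
        return event

    @property
    def events(self) -> tuple[AuditEvent, ...]:
        return tuple(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self):
        return iter(self._events)

    def record(
        self,
        action: str,
        subject: str,
        *,
        timestamp,
        actor_id: str = "system",
        actor_role: Role = Role.DATA_MANAGER,
        **payload,
    ) -> AuditEvent:
        return self.append(
            AuditEvent(
                timestamp=str(timestamp),
                actor_id=actor_id,
                actor_role=actor_role,
                action=action,
                subject=subject,
                payload=payload,
            )
        )

    def to_jsonl(self) -> str:
        return "\n".join(e.to_json() for e in self._events) + ("\n" if self._events else "")

    @classmethod
    def from_jsonl(cls, text: str) -> "AuditLog":
        events = []
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            d["actor_role"] = Role(d["actor_role"])
            events.append(AuditEvent(**d))
        return cls(events)


# --------------------------------------------------------------------------
# Eligibility screening
# --------------------------------------------------------------------------

#: Printed thresholds, all boundaries inclusive ("or more" / "or less").
WAIST_CM_MIN = {Sex.FEMALE: 85.0, Sex.MALE: 100.0}
GLYCEMIA_MIN = 100.0
TRIGLYCERIDES_MIN = 150.0
HDL_MAX = {Sex.FEMALE: 50.0, Sex.MALE: 40.0}
SYSTOLIC_MIN = 130.0
DIASTOLIC_MIN = 85.0
GLYCEMIA_EXCLUSION = 126.0  # strictly above, on two repeated samples
CREATININE_EXCLUSION_UMOL_L = 124.0  # strictly above
MIN_CRITERIA_FOR_SYNDROME = 3


def _require(m: BaselineMeasures, *names: str) -> None:
    for name in names:
        if getattr(m, name) is None:
            raise ValidationError(f"missing required baseline field: {name}")


def count_metabolic_criteria(m: BaselineMeasures, sex: Sex) -> int:
    """Number (0-5) of metabolic-syndrome criteria satisfied at baseline.

    The five disorders are abdominal obesity, hyperglycemia,
    hypertriglyceridemia (or treatment), low HDL (or cholesterol treatment)
    and high blood pressure (either bound, or treatment).
    """
    _require(
        m,
        "waist_cm",
        "glycemia_mg_dl",
        "triglycerides_mg_dl",
        "hdl_mg_dl",
        "systolic_mmHg",
        "diastolic_mmHg",
    )
    sex = Sex(sex)
    n = 0
    if m.waist_cm >= WAIST_CM_MIN[sex]:
        n += 1
    if m.glycemia_mg_dl >= GLYCEMIA_MIN:
        n += 1
    if m.triglycerides_mg_dl >= TRIGLYCERIDES_MIN or m.on_tg_treatment:
        n += 1
    if m.hdl_mg_dl <= HDL_MAX[sex] or m.on_chol_treatment:
        n += 1
    if m.systolic_mmHg >= SYSTOLIC_MIN or m.diastolic_mmHg >= DIASTOLIC_MIN or m.on_bp_treatment:
        n += 1
    return n


def check_exclusions(m: BaselineMeasures) -> list[str]:
    """Names of every violated exclusion rule (empty list = eligible).

    The hyperglycemia exclusion requires *two* repeated samples above
    126 mg/dL; a single high value with a normal (or missing) repeat does
    not exclude.
    """
    violated = []
    if (
        m.glycemia_mg_dl is not None
        and m.repeat_glycemia_mg_dl is not None
        and m.glycemia_mg_dl > GLYCEMIA_EXCLUSION
        and m.repeat_glycemia_mg_dl > GLYCEMIA_EXCLUSION
    ):
        violated.append("glycemia")
    if m.on_metformin:
        violated.append("metformin")
    if m.recent_cancer:
        violated.append("cancer")
    if m.creatinine_umol_l is not None and m.creatinine_umol_l > CREATININE_EXCLUSION_UMOL_L:
        violated.append("creatinine")
    if m.proteinuria:
        violated.append("proteinuria")
    if m.on_excluded_drugs:
        violated.append("concomitant_drugs")
    if m.excess_alcohol:
        violated.append("alcohol")
    return violated


def is_eligible(m: BaselineMeasures, sex: Sex) -> bool:
    """Metabolic syndrome present (>= 3 criteria) and no exclusion violated."""
    return count_metabolic_criteria(m, sex) >= MIN_CRITERIA_FOR_SYNDROME and not check_exclusions(m)


# --------------------------------------------------------------------------
# State machine
# --------------------------------------------------------------------------


def transition(
    p: Participant,
    event: TrialEvent,
    when: date,
    log: Optional[AuditLog] = None,
    *,
    actor_id: str = "system",
    actor_role: Role = Role.DATA_MANAGER,
    **payload,
) -> tuple[Participant, AuditEvent]:
    """Advance ``p`` along the protocol flow.

    Raises :class:`StateError` for any (state, event) pair not in the
    transition table; terminal states accept no event.  The participant is
    mutated in place and the emitted audit event is returned alongside it.
    """
    event = TrialEvent(event)
    key = (p.state, event)
    if key not in TRANSITIONS:
        raise StateError(
            f"event '{event.value}' is illegal from state '{p.state.value}' "
            f"for participant {p.participant_id}"
        )
    old = p.state
    p.state = TRANSITIONS[key]
    audit = AuditEvent(
        timestamp=str(when),
        actor_id=actor_id,
        actor_role=actor_role,
        action="state_transition",
        subject=p.participant_id,
        payload={"event": event.value, "from": old.value, "to": p.state.value, **payload},
    )
    if log is not None:
        log.append(audit)
    return p, audit


def set_dose(
    p: Participant,
    level: DoseLevel,
    *,
    actor_id: str,
    actor_role: Role,
    when: date,
    log: Optional[AuditLog] = None,
) -> tuple[Participant, AuditEvent]:
    """Adjust a participant's dose (e.g. to a half-dose).  PI only."""
    if Role(actor_role) is not Role.PI:
        raise AuthorizationError(
            f"only the PI may adjust dosage; actor role was '{Role(actor_role).value}'"
        )
    if p.state not in RANDOMIZED_STATES:
        raise StateError(
            f"cannot set dose before treatment randomization (state {p.state.value})"
        )
    old = p.dose_level
    p.dose_level = DoseLevel(level)
    audit = AuditEvent(
        timestamp=str(when),
        actor_id=actor_id,
        actor_role=Role.PI,
        action="dose_change",
        subject=p.participant_id,
        payload={"from": old.value, "to": p.dose_level.value},
    )
    if log is not None:
        log.append(audit)
    return p, audit


def replay_states(log: AuditLog) -> dict[str, ParticipantState]:
    """Reconstruct every participant's current state from the audit log.

    Event-sourcing round trip: replaying only the ``state_transition``
    events must reproduce the in-memory states exactly.
    """
    states: dict[str, ParticipantState] = {}
    for e in log:
        if e.action == "registration":
            states[e.subject] = ParticipantState.REGISTERED
        elif e.action == "state_transition":
            states[e.subject] = ParticipantState(e.payload["to"])
    return states
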