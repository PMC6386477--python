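"""The trial aggregate: participants, blinding, warehouse, ledgers, audit.

A thin coordination layer — every rule lives in the module that owns it
(eligibility and states in :mod:`.core`, arm assignment in
:mod:`.randomization`, the blind in :mod:`.blinding`, stock in
:mod:`.supply`, ordering in :mod:`.forecast`).
"""

from __future__ import annotations

import random
from datetime import date
from typing import Optional

from . import forecast, sealing
from .blinding import TrialBlinding, generate_allocation_list, export_manufacturer_list
from .core import (
    AuditLog,
    BaselineMeasures,
    DoseLevel,
    Participant,
    ParticipantState,
    Role,
    Sex,
    TrialEvent,
    check_exclusions,
    count_metabolic_criteria,
    is_eligible,
    set_dose,
    transition,
)
from .errors import StateError, UnknownCodeError, ValidationError
from .randomization import StratumLedger, balance_report, randomize_diet, randomize_treatment
from .supply import Warehouse


class Trial:
    """In-memory trial state; persisted by :mod:`trialkit.store`."""

    def __init__(
        self,
        seed: int = 0,
        *,
        allocation_bottles: int = 0,
        key: Optional[bytes] = None,
    ) -> None:
        self.seed = int(seed)
        self.key = key if key is not None else sealing.derive_key(self.seed)
        self.participants: dict[str, Participant] = {}
        self.ledger = StratumLedger()
        self.audit = AuditLog()
        self.rng_diet = random.Random((self.seed * 2654435761 + 101) % 2**31)
        self.rng_treatment = random.Random((self.seed * 2654435761 + 202) % 2**31)
        self.blinding: Optional[TrialBlinding] = None
        self._allocation_blocks = None
        if allocation_bottles:
            self.generate_allocation(allocation_bottles)
        self.warehouse = Warehouse(self.blinding.bottles if self.blinding else {})

    # -- setup -------------------------------------------------------------
    def generate_allocation(self, n_bottles: int) -> None:
        alloc_seed = (self.seed * 2654435761 + 303) % 2**31
        blocks = generate_allocation_list(n_bottles, alloc_seed)
        self._allocation_blocks = blocks
        self.blinding = TrialBlinding.from_allocation(blocks, self.key, self.seed)
        if hasattr(self, "warehouse"):
            self.warehouse = Warehouse(self.blinding.bottles)

    def manufacturer_list(self):
        """Plaintext (code, treatment) export; only valid at generation time."""
        if self._allocation_blocks is None:
            raise StateError("allocation list not generated in this session")
        return export_manufacturer_list(self._allocation_blocks)

    def unloaded_codes(self, n: int) -> list[str]:
        """Next ``n`` not-yet-loaded bottle codes, in generation order."""
        from .blinding import BottleStatus

        out = []
        for code, b in self.blinding.bottles.items():
            if b.status is BottleStatus.GENERATED:
                out.append(code)
                if len(out) == n:
                    return out
        raise ValidationError(
            f"allocation list exhausted: requested {n} unloaded bottles, found {len(out)}"
        )

    # -- participant lifecycle ---------------------------------------------
    def register(
        self,
        participant_id: str,
        sex: Sex,
        birth_date: date,
        consent_date: date,
        family_id: Optional[str] = None,
    ) -> Participant:
        if participant_id in self.participants:
            raise ValidationError(f"participant {participant_id} already registered")
        p = Participant(
            participant_id=participant_id,
            sex=Sex(sex),
            birth_date=birth_date,
            consent_date=consent_date,
            family_id=family_id,
        )
        self.participants[participant_id] = p
        self.audit.record(
            "registration",
            participant_id,
            timestamp=consent_date,
            sex=p.sex.value,
            family_id=family_id,
        )
        return p

    def get(self, participant_id: str) -> Participant:
        try:
            return self.participants[participant_id]
        except KeyError:
            raise UnknownCodeError(f"unknown participant: {participant_id}") from None

    def randomize_diet(self, participant_id: str, when: date):
        return randomize_diet(
            self.get(participant_id), self.ledger, self.rng_diet, when=when, log=self.audit
        )

    def screen(self, participant_id: str, measures: BaselineMeasures, when: date) -> bool:
        """Apply eligibility to a diet-randomized participant; start run-in
        on a pass, screen-fail otherwise.  Returns eligibility."""
        p = self.get(participant_id)
        ok = is_eligible(measures, p.sex)
        event = TrialEvent.SCREENING_PASSED if ok else TrialEvent.SCREEN_FAILURE
        transition(
            p,
            event,
            when,
            self.audit,
            criteria_met=count_metabolic_criteria(measures, p.sex),
            exclusions=check_exclusions(measures),
        )
        if ok and p.anniversary_date is None:
            p.anniversary_date = date(when.year + 1, when.month, min(when.day, 28))
        return ok

    def randomize_treatment(self, participant_id: str, when: date, **gates):
        return randomize_treatment(
            self.get(participant_id),
            self.ledger,
            self.rng_treatment,
            when=when,
            log=self.audit,
            **gates,
        )

    def dispense(self, participant_id: str, when: date):
        return self.warehouse.dispense(self.get(participant_id), when, self.audit)

    def set_dose(self, participant_id: str, level: DoseLevel, *, actor_id: str, actor_role: Role, when: date):
        return set_dose(
            self.get(participant_id),
            level,
            actor_id=actor_id,
            actor_role=actor_role,
            when=when,
            log=self.audit,
        )

    def break_blind(self, participant_id: str, *, actor_id: str, actor_role: Role, reason: str, when: date):
        if self.blinding is None:
            raise StateError("no sealed allocation in this trial")
        return self.blinding.break_blind(
            self.get(participant_id),
            actor_id=actor_id,
            actor_role=actor_role,
            reason=reason,
            key=self.key,
            when=when,
            log=self.audit,
        )

    # -- reporting and forecasting -----------------------------------------
    def balance(self):
        return balance_report(self.participants.values())

    def estimate_order(self, today: date, **kwargs) -> forecast.OrderEstimate:
        est = forecast.estimate_order(
            self.participants.values(),
            self.warehouse.next_due,
            self.ledger.treatment_dates,
            today,
            **kwargs,
        )
        return est

    def order_decision(self, today: date, **kwargs) -> forecast.OrderDecision:
        return forecast.order_trigger(
            self.warehouse, self.participants.values(), today, **kwargs
        )

    def active_count(self, *states: ParticipantState) -> int:
        wanted = set(states)
        return sum(1 for p in self.participants.values() if p.state in wanted)
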