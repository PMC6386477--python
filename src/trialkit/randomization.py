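"""Balanced covariate-adaptive randomization for the two trial arms.

Two distinct randomizations are performed:

* **Diet** (at registration): blue = active lifestyle intervention, green =
  control.  Balancing features are sex and family membership — all members
  of one family receive the proband's arm.  Probands are assigned by
  deterministic minimization, lexicographic over (overall proband margin,
  proband margin within the participant's sex), with exact ties broken by a
  seeded fair coin.  This keeps the overall proband imbalance at most 1 at
  all times.

* **Treatment** (after the run-in): blinded labels X/Y.  Balancing features
  are sex and age group (up to 67 / over 67 years at randomization).  Labels
  are assigned by minimization: choose the label minimizing the worst
  post-assignment margin imbalance, then the sum of margin imbalances, then
  a seeded coin.

Assignments are immutable once made; the balance statistics are inspectable
at any time through :func:`balance_report`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

import pandas as pd

from .core import (
    AuditLog,
    DietArm,
    Participant,
    ParticipantState,
    Sex,
    TrialEvent,
    transition,
)
from .errors import GatingError, StateError

AGE_GROUP_BOUNDARY = 67  # "up to 67" is inclusive
TREATMENT_LABELS = ("X", "Y")


def age_group(age_years: int) -> str:
    return "le67" if age_years <= AGE_GROUP_BOUNDARY else "gt67"


@dataclass
class StratumLedger:
    """Per-margin assignment counters for both randomizations.

    Diet counters cover probands only (familiars inherit the proband's arm
    and would otherwise bias the margins by family size); treatment counters
    cover every randomized participant.
    """

    diet_sex: dict = field(default_factory=dict)  # (sex, arm) -> n, probands only
    treatment_sex: dict = field(default_factory=dict)  # (sex, label) -> n
    treatment_age: dict = field(default_factory=dict)  # (age group, label) -> n
    family_arms: dict = field(default_factory=dict)  # family_id -> DietArm
    treatment_dates: list = field(default_factory=list)  # randomization dates, for accrual trend

    # -- diet margins ------------------------------------------------------
    def diet_count(self, sex: Sex, arm: DietArm) -> int:
        return self.diet_sex.get((Sex(sex).value, DietArm(arm).value), 0)

    def diet_overall(self, arm: DietArm) -> int:
        return sum(self.diet_count(s, arm) for s in Sex)

    def record_diet(self, sex: Sex, arm: DietArm) -> None:
        key = (Sex(sex).value, DietArm(arm).value)
        self.diet_sex[key] = self.diet_sex.get(key, 0) + 1

    # -- treatment margins -------------------------------------------------
    def treatment_count_sex(self, sex: Sex, label: str) -> int:
        return self.treatment_sex.get((Sex(sex).value, label), 0)

    def treatment_count_age(self, group: str, label: str) -> int:
        return self.treatment_age.get((group, label), 0)

    def record_treatment(self, sex: Sex, group: str, label: str, when: Optional[date] = None) -> None:
        ks = (Sex(sex).value, label)
        ka = (group, label)
        self.treatment_sex[ks] = self.treatment_sex.get(ks, 0) + 1
        self.treatment_age[ka] = self.treatment_age.get(ka, 0) + 1
        if when is not None:
            self.treatment_dates.append(when)


def randomize_diet(
    p: Participant,
    ledger: StratumLedger,
    rng: random.Random,
    *,
    when: date,
    log: Optional[AuditLog] = None,
) -> DietArm:
    """Assign the diet arm at registration.

    Familiars inherit the family's existing arm without touching the
    minimization counters; probands are assigned by minimization.
    """
    if p.state is not ParticipantState.REGISTERED or p.diet_arm is not None:
        raise StateError(
            f"participant {p.participant_id} already diet-randomized (state {p.state.value})"
        )
    if p.family_id is not None and p.family_id in ledger.family_arms:
        arm = ledger.family_arms[p.family_id]
        p.is_proband = False
    else:
        p.is_proband = True
        scores = {}
        for arm_c in DietArm:
            overall = abs(
                ledger.diet_overall(arm_c) + 1 - ledger.diet_overall(_other_arm(arm_c))
            )
            within_sex = abs(
                ledger.diet_count(p.sex, arm_c) + 1 - ledger.diet_count(p.sex, _other_arm(arm_c))
            )
            scores[arm_c] = (overall, within_sex)
        arm = _argmin(scores, rng)
        ledger.record_diet(p.sex, arm)
        if p.family_id is not None:
            ledger.family_arms[p.family_id] = arm
    p.diet_arm = arm
    transition(
        p,
        TrialEvent.DIET_RANDOMIZATION,
        when,
        log,
        arm=arm.value,
        proband=p.is_proband,
    )
    return arm


def randomize_treatment(
    p: Participant,
    ledger: StratumLedger,
    rng: random.Random,
    *,
    when: date,
    registration_complete: bool = True,
    eligible: bool = True,
    adverse_event_in_run_in: bool = False,
    log: Optional[AuditLog] = None,
) -> str:
    """Assign the blinded treatment label after a clean run-in.

    Gated on: completed registration data, eligibility satisfied, and no
    adverse events in the 30-day run-in.  The returned label is the blinded
    alias (X/Y), never a drug name.
    """
    if p.state is not ParticipantState.RUN_IN:
        raise StateError(
            f"participant {p.participant_id} is not at the end of run-in "
            f"(state {p.state.value})"
        )
    if adverse_event_in_run_in:
        raise GatingError("adverse event during the 30-day run-in blocks randomization")
    if not registration_complete:
        raise GatingError(
            "registration data incomplete (lifestyle, 24-h diet diary, "
            "physical-activity diary, concomitant medications)"
        )
    if not eligible:
        raise GatingError("eligibility criteria not satisfied")
    group = age_group(p.age_at(when))
    scores = {}
    for label in TREATMENT_LABELS:
        other = _other_label(label)
        ds = ledger.treatment_count_sex(p.sex, label) + 1 - ledger.treatment_count_sex(p.sex, other)
        da = ledger.treatment_count_age(group, label) + 1 - ledger.treatment_count_age(group, other)
        scores[label] = (max(abs(ds), abs(da)), abs(ds) + abs(da))
    label = _argmin(scores, rng)
    ledger.record_treatment(p.sex, group, label, when)
    p.treatment_label = label
    p.randomization_date = when
    transition(
        p,
        TrialEvent.TREATMENT_RANDOMIZATION,
        when,
        log,
        label=label,
        age_group=group,
    )
    return label


def _other_arm(arm: DietArm) -> DietArm:
    return DietArm.GREEN if arm is DietArm.BLUE else DietArm.BLUE


def _other_label(label: str) -> str:
    return "Y" if label == "X" else "X"


def _argmin(scores: dict, rng: random.Random):
    best = min(scores.values())
    candidates = [k for k, v in scores.items() if v == best]
    if len(candidates) == 1:
        return candidates[0]
    return candidates[rng.randrange(len(candidates))]


# --------------------------------------------------------------------------
# Balance reporting
# --------------------------------------------------------------------------


@dataclass
class BalanceReport:
    """Diet-arm balance in the proband/familiar x sex x arm layout."""

    table: pd.DataFrame  # rows proband/familiar/total; cols (arm, sex) + total
    family_consistent: bool

    @property
    def proband_total(self) -> int:
        return int(self.table.loc["proband", ("total", "")])

    @property
    def familiar_total(self) -> int:
        return int(self.table.loc["familiar", ("total", "")])

    @property
    def grand_total(self) -> int:
        return int(self.table.loc["total", ("total", "")])

    def arm_total(self, arm: DietArm, role: str = "total") -> int:
        a = DietArm(arm).value
        return int(sum(self.table.loc[role, (a, s.value)] for s in Sex))

    @property
    def proband_imbalance(self) -> int:
        return abs(self.arm_total(DietArm.BLUE, "proband") - self.arm_total(DietArm.GREEN, "proband"))

    def to_csv(self) -> str:
        return self.table.to_csv()


def balance_report(participants: Iterable[Participant]) -> BalanceReport:
    """Cross-tabulate diet arms by enrolment role and sex, with totals."""
    cols = pd.MultiIndex.from_product(
        [[a.value for a in DietArm], [s.value for s in Sex]], names=["arm", "sex"]
    )
    table = pd.DataFrame(0, index=["proband", "familiar"], columns=cols)
    families: dict[str, set] = {}
    for p in participants:
        if p.diet_arm is None:
            continue
        row = "proband" if p.is_proband else "familiar"
        table.loc[row, (p.diet_arm.value, p.sex.value)] += 1
        if p.family_id is not None:
            families.setdefault(p.family_id, set()).add(p.diet_arm)
    table.loc["total"] = table.sum()
    table[("total", "")] = table.sum(axis=1)
    consistent = all(len(arms) == 1 for arms in families.values())
    return BalanceReport(table=table, family_consistent=consistent)
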