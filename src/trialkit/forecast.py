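"""Demand estimation, order triggering and the wastage counterfactual.

The order quantity is ``(A + B1 + B2) - C``:

* ``A`` — bottles due within the horizon for already-randomized active
  participants, from each participant's own dispensing calendar;
* ``B1`` — bottles for projected future randomizations: the trailing mean
  of monthly treatment randomizations times the horizon times the
  first-year bottle need of one full-dose participant;
* ``B2`` — run-in units for participants currently between screening and
  randomization (one 30-tablet unit each);
* ``C`` — bottles not needed because of expected withdrawals, the drop-out
  rate applied to A + B1.

Orders are triggered at least 30 days before the last batch expires, or
whenever a stockout is projected within the supplier's delivery lead time
(60 days).

The patients'-pack counterfactual prices the wasteful baseline policy —
one full-dose bottle per month for every consented code, minus an assumed
loss to follow-up — and the savings report compares it with what on-demand
supply actually dispensed plus the projected bottles to conclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Iterator, Optional

from .core import DoseLevel, Participant, ParticipantState, RANDOMIZED_STATES
from .errors import ValidationError
from .supply import MONTH_DAYS, SupplyStep, Warehouse, required_supply

#: Bottles one never-interrupted full-dose participant needs in the first
#: 372 days after randomization: 1 (step 1) + 1 (step 2) + 6 + 6 (the two
#: maintenance supplies falling at days 93 and 279).
FIRST_YEAR_BOTTLES = 14

DEFAULT_DROPOUT_RATE = 0.032  # observed annual drop-out
DEFAULT_ACCRUAL_WINDOW_MONTHS = 6
DEFAULT_HORIZON_MONTHS = 12
DEFAULT_DELIVERY_LEAD_DAYS = 60  # supplier must deliver within 60 days
DEFAULT_AGREEMENT_LEAD_DAYS = 30  # order scheduling agreed in the contract
DEFAULT_EXPIRY_MARGIN_DAYS = 30  # estimate needs >= 30 days before last expiry


@dataclass(frozen=True)
class OrderEstimate:
    """Components of one supply order; ``total`` is exactly A+B1+B2-C."""

    A: int
    B1: int
    B2: int
    C: int
    horizon_months: int = DEFAULT_HORIZON_MONTHS

    def __post_init__(self) -> None:
        for name in ("A", "B1", "B2", "C"):
            if getattr(self, name) < 0:
                raise ValidationError(f"order component {name} must be non-negative")
        if self.total < 0:
            raise ValidationError("order total (A+B1+B2)-C must be non-negative")

    @property
    def total(self) -> int:
        return self.A + self.B1 + self.B2 - self.C


@dataclass(frozen=True)
class SavingsReport:
    theoretical_pp: int
    dispensed: int
    projected_to_end: int
    unit_cost: float
    bottles_saved: int
    savings_pct: float
    budget_saving: float
    budget_saving_rounded_thousand: int


@dataclass(frozen=True)
class OrderDecision:
    order_now: bool
    latest_order_date: Optional[date]
    reasons: tuple[str, ...]


# --------------------------------------------------------------------------
# Per-participant dispensing calendar
# --------------------------------------------------------------------------

_NEXT_STEP = {
    SupplyStep.STEP_1: SupplyStep.STEP_2,
    SupplyStep.STEP_2: SupplyStep.MAINTENANCE,
    SupplyStep.MAINTENANCE: SupplyStep.MAINTENANCE,
}

_FIRST_PENDING_STEP = {
    ParticipantState.TREATMENT_RANDOMIZED: SupplyStep.STEP_1,
    ParticipantState.SUPPLY_STEP_1: SupplyStep.STEP_2,
    ParticipantState.SUPPLY_STEP_2: SupplyStep.MAINTENANCE,
    ParticipantState.MAINTENANCE: SupplyStep.MAINTENANCE,
}


def dispensing_calendar(
    first_step: SupplyStep,
    first_due: date,
    treatment_end: date,
    dose_level: DoseLevel = DoseLevel.FULL,
) -> Iterator[tuple[date, SupplyStep, int, int]]:
    """Scheduled dispensations (date, step, bottles, days) until treatment end.

    A dispensation takes place whenever its due date falls strictly before
    the planned treatment end; the current dose level is assumed to hold
    for the rest of the schedule.
    """
    step, due = first_step, first_due
    while due < treatment_end:
        n, days, _ = required_supply(step, dose_level)
        yield due, step, n, days
        due = due + timedelta(days=days)
        step = _NEXT_STEP[step]


def scheduled_bottles(
    p: Participant,
    next_due: Optional[date],
    window_start: date,
    window_end: date,
) -> int:
    """Bottles due to one randomized active participant within a window."""
    if p.state not in RANDOMIZED_STATES or p.treatment_end_date is None:
        return 0
    first_step = _FIRST_PENDING_STEP[p.state]
    first_due = next_due if next_due is not None else window_start
    total = 0
    for due, _, n, _ in dispensing_calendar(first_step, first_due, p.treatment_end_date, p.dose_level):
        if due >= window_end:
            break
        if due >= window_start:
            total += n
    return total


# --------------------------------------------------------------------------
# The order formula
# --------------------------------------------------------------------------


def estimate_order(
    participants: Iterable[Participant],
    next_due: dict[str, date],
    randomization_dates: Iterable[date],
    today: date,
    *,
    horizon_months: int = DEFAULT_HORIZON_MONTHS,
    accrual_window_months: int = DEFAULT_ACCRUAL_WINDOW_MONTHS,
    dropout_rate: float = DEFAULT_DROPOUT_RATE,
) -> OrderEstimate:
    """Compute (A + B1 + B2) - C for the given horizon."""
    if horizon_months <= 0:
        raise ValidationError("horizon must be positive")
    if not 0 <= dropout_rate < 1:
        raise ValidationError("dropout rate must be in [0, 1)")
    window_end = today + timedelta(days=horizon_months * MONTH_DAYS)
    a = 0
    b2 = 0
    for p in participants:
        if p.state is ParticipantState.RUN_IN:
            b2 += 1
        elif p.state in RANDOMIZED_STATES:
            a += scheduled_bottles(p, next_due.get(p.participant_id), today, window_end)
    window_start = today - timedelta(days=accrual_window_months * MONTH_DAYS)
    recent = sum(1 for d in randomization_dates if window_start <= d < today)
    monthly_rate = recent / accrual_window_months
    b1 = round(monthly_rate * horizon_months * FIRST_YEAR_BOTTLES)
    c = min(round(dropout_rate * (a + b1)), a + b1)
    return OrderEstimate(A=a, B1=b1, B2=b2, C=c, horizon_months=horizon_months)


def order_trigger(
    warehouse: Warehouse,
    participants: Iterable[Participant],
    today: date,
    *,
    lead_days: int = DEFAULT_DELIVERY_LEAD_DAYS,
    expiry_margin_days: int = DEFAULT_EXPIRY_MARGIN_DAYS,
) -> OrderDecision:
    """Should an order go out now, and what is the latest safe order date?

    Order now if today is within ``expiry_margin_days`` of the last batch
    expiry, or if replaying the scheduled FEFO demand against current stock
    projects a stockout within the supplier lead time.
    """
    reasons = []
    deadlines = []
    latest_expiry = warehouse.latest_stock_expiry()
    if latest_expiry is not None:
        expiry_deadline = latest_expiry - timedelta(days=expiry_margin_days)
        deadlines.append(expiry_deadline)
        if today >= expiry_deadline:
            reasons.append(
                f"last batch expires {latest_expiry}, within {expiry_margin_days} days"
            )
    stockout = projected_stockout_date(
        warehouse, participants, today, horizon_days=lead_days + MONTH_DAYS
    )
    if stockout is not None:
        deadlines.append(stockout - timedelta(days=lead_days))
        if stockout <= today + timedelta(days=lead_days):
            reasons.append(f"stockout projected on {stockout}, within the {lead_days}-day lead")
    if latest_expiry is None and any(
        p.state in RANDOMIZED_STATES or p.state is ParticipantState.RUN_IN for p in participants
    ):
        reasons.append("no blinded stock on hand with active participants")
        deadlines.append(today)
    return OrderDecision(
        order_now=bool(reasons),
        latest_order_date=min(deadlines) if deadlines else None,
        reasons=tuple(reasons),
    )


def projected_stockout_date(
    warehouse: Warehouse,
    participants: Iterable[Participant],
    today: date,
    *,
    horizon_days: int,
) -> Optional[date]:
    """First date within the horizon on which scheduled FEFO demand fails.

    Replays every active participant's calendar against a snapshot of the
    in-stock expiries per blinded label, consuming earliest-expiring
    eligible bottles first, exactly as dispensing would.
    """
    window_end = today + timedelta(days=horizon_days)
    events: list[tuple[date, str, int, int]] = []  # (date, label, bottles, days)
    for p in participants:
        if p.state not in RANDOMIZED_STATES or p.treatment_end_date is None:
            continue
        first_due = warehouse.next_due.get(p.participant_id, today)
        for due, _, n, days in dispensing_calendar(
            _FIRST_PENDING_STEP[p.state], first_due, p.treatment_end_date, p.dose_level
        ):
            if due >= window_end:
                break
            if due >= today:
                events.append((due, p.treatment_label, n, days))
    events.sort(key=lambda e: (e[0], e[1]))
    stock = {label: warehouse.in_stock_expiries(label) for label in {e[1] for e in events}}
    for due, label, n, days in events:
        covers_until = due + timedelta(days=days)
        pool = stock[label]
        taken = 0
        i = 0
        while i < len(pool) and taken < n:
            if pool[i] >= covers_until:
                pool.pop(i)
                taken += 1
            else:
                i += 1  # short-dated: skipped, as the expiry guard would
        if taken < n:
            return due
    return None


# --------------------------------------------------------------------------
# Patients'-pack counterfactual and savings
# --------------------------------------------------------------------------


def patients_pack_requirement(n_participants: int, mean_months: float, loss_rate: float) -> int:
    """Bottles a patients'-pack policy would order for the whole cohort.

    One full-dose bottle per month of treatment for every consented code,
    discounted by the assumed loss to follow-up, rounded to the nearest
    bottle.
    """
    if n_participants <= 0 or mean_months <= 0:
        raise ValidationError("participants and months must be positive")
    if not 0 <= loss_rate < 1:
        raise ValidationError("loss rate must be in [0, 1)")
    return round(n_participants * mean_months * (1.0 - loss_rate))


def savings_report(
    theoretical_pp: int,
    dispensed: int,
    projected_to_end: int,
    unit_cost: float,
) -> SavingsReport:
    """On-demand vs patients'-pack savings, percentage to one decimal."""
    if theoretical_pp <= 0:
        raise ValidationError("savings percentage undefined for a zero patients'-pack baseline")
    bottles_saved = theoretical_pp - dispensed - projected_to_end
    pct = round(100.0 * bottles_saved / theoretical_pp, 1)
    budget = bottles_saved * unit_cost
    return SavingsReport(
        theoretical_pp=theoretical_pp,
        dispensed=dispensed,
        projected_to_end=projected_to_end,
        unit_cost=unit_cost,
        bottles_saved=bottles_saved,
        savings_pct=pct,
        budget_saving=budget,
        budget_saving_rounded_thousand=int(round(budget / 1000.0)) * 1000,
    )


def survival_weighted_projection(
    participants: Iterable[Participant],
    next_due: dict[str, date],
    today: date,
    *,
    annual_dropout_rate: float = DEFAULT_DROPOUT_RATE,
    run_in_end: Optional[dict[str, date]] = None,
    pre_randomization_survival: float = 1.0,
    treatment_months: int = 36,
) -> int:
    """Expected bottles still to dispense before every participant concludes.

    Each future scheduled dispensation is weighted by the probability the
    participant is still on study when it falls due, under a constant
    drop-out hazard equivalent to ``annual_dropout_rate`` per 372-day year.
    Participants still in run-in contribute their whole post-randomization
    calendar scaled by ``pre_randomization_survival`` (the probability they
    survive run-in and screening gates).
    """
    if not 0 <= annual_dropout_rate < 1:
        raise ValidationError("dropout rate must be in [0, 1)")
    daily_log_surv = math.log(1.0 - annual_dropout_rate) / (12 * MONTH_DAYS)
    expected = 0.0
    for p in participants:
        if p.state in RANDOMIZED_STATES and p.treatment_end_date is not None:
            first_due = next_due.get(p.participant_id, today)
            for due, _, n, _ in dispensing_calendar(
                _FIRST_PENDING_STEP[p.state], first_due, p.treatment_end_date, p.dose_level
            ):
                if due < today:
                    due = today
                dt = (due - today).days
                expected += n * math.exp(daily_log_surv * dt)
        elif p.state is ParticipantState.RUN_IN and run_in_end is not None:
            start = run_in_end.get(p.participant_id)
            if start is None or p.treatment_end_date is not None:
                continue
            end = start + timedelta(days=treatment_months * MONTH_DAYS)
            for due, _, n, _ in dispensing_calendar(SupplyStep.STEP_1, start, end, p.dose_level):
                dt = max((due - today).days, 0)
                expected += n * pre_randomization_survival * math.exp(daily_log_surv * dt)
    return round(expected)
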