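"""The virtual warehouse: batches, the per-state medication schedule,
FEFO dispensing with expiry guards, disposal and the allocation register.

Supply arithmetic uses the 62-tablet bottle and a 31-day month throughout
(62 tablets at two per day is exactly one month).  The schedule per state:

* run-in: one open-label 500 mg unit, 30 tablets / 30 days (its own stock
  line, never part of the blinded allocation list);
* first supply: 1 bottle, one 850 mg tablet/day, 62 days;
* second supply: 1 bottle, two tablets/day (1700 mg/day), 31 days;
* maintenance: a six-month supply — 6 bottles (186 days) at full dose,
  3 bottles at half dose.

A bottle is eligible for a dispensation only if it expires no earlier than
the end of the period the dispensation covers, so a participant can never
be holding expired drug.  Among eligible bottles the earliest-expiring are
dispensed first (FEFO).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .blinding import Bottle, BottleStatus, TABLETS_PER_BOTTLE
from .core import (
    AuditLog,
    DoseLevel,
    Participant,
    ParticipantState,
    Role,
    TrialEvent,
    transition,
)
from .errors import (
    ExpiryError,
    StateError,
    StockoutError,
    UnknownCodeError,
    ValidationError,
)

MONTH_DAYS = 31
MIN_SHELF_LIFE_MONTHS = 12
RUN_IN_PRODUCT = "RUNIN500"  # open-label 500 mg run-in units, 30 tablets
RUN_IN_DAYS = 30


class SupplyStep(str, Enum):
    RUN_IN = "run_in"
    STEP_1 = "step_1"
    STEP_2 = "step_2"
    MAINTENANCE = "maintenance"


#: state -> (step dispensed next, state-machine event it triggers)
_STEP_FOR_STATE = {
    ParticipantState.TREATMENT_RANDOMIZED: (SupplyStep.STEP_1, TrialEvent.FIRST_SUPPLY),
    ParticipantState.SUPPLY_STEP_1: (SupplyStep.STEP_2, TrialEvent.SECOND_SUPPLY),
    ParticipantState.SUPPLY_STEP_2: (SupplyStep.MAINTENANCE, TrialEvent.MAINTENANCE_SUPPLY),
    ParticipantState.MAINTENANCE: (SupplyStep.MAINTENANCE, TrialEvent.MAINTENANCE_SUPPLY),
}


def required_supply(step: SupplyStep, dose_level: DoseLevel = DoseLevel.FULL) -> tuple[int, int, int]:
    """(bottle count, days covered, tablets per day) for one dispensation."""
    try:
        step = SupplyStep(step)
        dose = DoseLevel(dose_level)
    except ValueError as e:
        raise ValidationError(str(e)) from None
    if step is SupplyStep.RUN_IN:
        return 1, RUN_IN_DAYS, 1
    if step is SupplyStep.STEP_1:
        return 1, 62, 1
    if step is SupplyStep.STEP_2:
        return 1, 31, 2
    if step is SupplyStep.MAINTENANCE:
        if dose is DoseLevel.FULL:
            return 6, 186, 2
        return 3, 186, 1
    raise ValidationError(f"unknown supply step: {step}")


@dataclass(frozen=True)
class Batch:
    """One delivery lot of blinded bottles."""

    batch_id: str
    order_id: str
    load_date: date
    expiry_date: date
    codes: tuple[str, ...]


@dataclass(frozen=True)
class RunInLot:
    lot_id: str
    load_date: date
    expiry_date: date
    units: int


@dataclass(frozen=True)
class Dispensation:
    participant_id: str
    date: date
    step: SupplyStep
    bottle_codes: tuple[str, ...]
    tablets_per_day: int
    days_covered: int
    next_due_date: date
    expiry_dates: tuple[date, ...] = ()
    product: str = "blinded"


class Warehouse:
    """Expiry-aware stock of blinded bottles plus the run-in product line."""

    def __init__(self, bottles: dict[str, Bottle], min_shelf_life_months: int = MIN_SHELF_LIFE_MONTHS):
        self.bottles = bottles
        self.min_shelf_life_months = min_shelf_life_months
        self.batches: dict[str, Batch] = {}
        self._heaps: dict[str, list] = {}  # blinded label -> [(expiry ordinal, code)]
        self.run_in_lots: list = []  # heap of [expiry ordinal, units remaining, lot_id]
        self.run_in_history: list[RunInLot] = []
        self.dispensations: list[Dispensation] = []
        self.next_due: dict[str, date] = {}
        self._run_in_supplied: set[str] = set()
        self._in_stock: set[str] = set()  # index over bottles in stock

    # -- loading -----------------------------------------------------------
    def load_batch(
        self,
        batch_id: str,
        order_id: str,
        load_date: date,
        expiry_date: date,
        codes: Iterable[str],
        log: Optional[AuditLog] = None,
    ) -> Batch:
        """Register a delivery: bottles become in-stock under the batch.

        A delivery whose expiry is under the minimum shelf life (twelve
        months by default) is rejected outright.
        """
        min_expiry = load_date + timedelta(days=self.min_shelf_life_months * MONTH_DAYS)
        if expiry_date < min_expiry:
            raise ValidationError(
                f"delivery rejected: expiry {expiry_date} is under the "
                f"{self.min_shelf_life_months}-month minimum shelf life "
                f"(needs >= {min_expiry})"
            )
        codes = tuple(codes)
        for code in codes:
            if code not in self.bottles:
                raise UnknownCodeError(f"unknown bottle code in delivery: {code}")
            if self.bottles[code].status is not BottleStatus.GENERATED:
                raise ValidationError(
                    f"bottle {code} already loaded (status {self.bottles[code].status.value})"
                )
        for code in codes:
            b = self.bottles[code]
            b.status = BottleStatus.IN_STOCK
            b.batch_id = batch_id
            b.expiry_date = expiry_date
            heapq.heappush(
                self._heaps.setdefault(b.blinded_label, []),
                (expiry_date.toordinal(), code),
            )
            self._in_stock.add(code)
        batch = Batch(batch_id, order_id, load_date, expiry_date, codes)
        self.batches[batch_id] = batch
        if log is not None:
            log.record(
                "batch_loaded",
                batch_id,
                timestamp=load_date,
                actor_role=Role.PHARMACIST,
                order_id=order_id,
                quantity=len(codes),
                expiry_date=str(expiry_date),
            )
        return batch

    def load_run_in_lot(
        self,
        lot_id: str,
        load_date: date,
        expiry_date: date,
        units: int,
        log: Optional[AuditLog] = None,
    ) -> RunInLot:
        min_expiry = load_date + timedelta(days=self.min_shelf_life_months * MONTH_DAYS)
        if expiry_date < min_expiry:
            raise ValidationError(
                f"run-in delivery rejected: expiry {expiry_date} is under the "
                f"{self.min_shelf_life_months}-month minimum shelf life"
            )
        if units <= 0:
            raise ValidationError("run-in lot must contain at least one unit")
        heapq.heappush(self.run_in_lots, [expiry_date.toordinal(), units, lot_id])
        lot = RunInLot(lot_id, load_date, expiry_date, units)
        self.run_in_history.append(lot)
        if log is not None:
            log.record(
                "batch_loaded",
                lot_id,
                timestamp=load_date,
                actor_role=Role.PHARMACIST,
                product=RUN_IN_PRODUCT,
                quantity=units,
                expiry_date=str(expiry_date),
            )
        return lot

    # -- stock queries -----------------------------------------------------
    def in_stock_count(self, label: Optional[str] = None) -> int:
        if label is None:
            return len(self._in_stock)
        return sum(1 for c in self._in_stock if self.bottles[c].blinded_label == label)

    def in_stock_expiries(self, label: str) -> list[date]:
        """Sorted expiry dates of in-stock bottles of one blinded label."""
        return sorted(
            self.bottles[c].expiry_date
            for c in self._in_stock
            if self.bottles[c].blinded_label == label
        )

    def latest_stock_expiry(self) -> Optional[date]:
        if not self._in_stock:
            return None
        return max(self.bottles[c].expiry_date for c in self._in_stock)

    def status_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in BottleStatus}
        for b in self.bottles.values():
            counts[b.status.value] += 1
        return counts

    def run_in_units(self) -> int:
        return sum(lot[1] for lot in self.run_in_lots)

    # -- dispensing --------------------------------------------------------
    def dispense(
        self,
        p: Participant,
        when: date,
        log: Optional[AuditLog] = None,
    ) -> Dispensation:
        """Issue the supply the participant's current state requires.

        Bottles are chosen FEFO among in-stock bottles of the participant's
        blinded label whose expiry covers the whole supplied period.
        Raises :class:`StateError` for blocked/terminal states,
        :class:`StockoutError` when total labelled stock is short, and
        :class:`ExpiryError` when stock exists but is all short-dated.
        """
        if p.state is ParticipantState.RUN_IN:
            return self._dispense_run_in(p, when, log)
        if p.state not in _STEP_FOR_STATE:
            raise StateError(
                f"participant {p.participant_id} cannot receive supply in "
                f"state {p.state.value}"
            )
        if p.treatment_label is None:
            raise StateError(f"participant {p.participant_id} has no blinded label")
        step, event = _STEP_FOR_STATE[p.state]
        n_bottles, days, tablets = required_supply(step, p.dose_level)
        covers_until = when + timedelta(days=days)
        taken = self._take_fefo(p.treatment_label, n_bottles, covers_until)
        for code in taken:
            self.bottles[code].status = BottleStatus.DISPENSED
            self._in_stock.discard(code)
        next_due = when + timedelta(days=days)
        disp = Dispensation(
            participant_id=p.participant_id,
            date=when,
            step=step,
            bottle_codes=tuple(taken),
            tablets_per_day=tablets,
            days_covered=days,
            next_due_date=next_due,
            expiry_dates=tuple(self.bottles[c].expiry_date for c in taken),
        )
        self.dispensations.append(disp)
        self.next_due[p.participant_id] = next_due
        transition(p, event, when, log, actor_role=Role.PHARMACIST)
        if log is not None:
            log.record(
                "dispensation",
                p.participant_id,
                timestamp=when,
                actor_role=Role.PHARMACIST,
                step=step.value,
                bottle_codes=list(taken),
                tablets_per_day=tablets,
                days_covered=days,
                next_due_date=str(next_due),
            )
        return disp

    def _dispense_run_in(self, p: Participant, when: date, log: Optional[AuditLog]) -> Dispensation:
        if p.participant_id in self._run_in_supplied:
            raise StateError(
                f"participant {p.participant_id} already received the run-in supply"
            )
        covers_until = when + timedelta(days=RUN_IN_DAYS)
        while self.run_in_lots and self.run_in_lots[0][1] == 0:
            heapq.heappop(self.run_in_lots)
        eligible = [lot for lot in self.run_in_lots if date.fromordinal(lot[0]) >= covers_until]
        if not eligible:
            if self.run_in_units() == 0:
                raise StockoutError("no run-in units in stock")
            raise ExpiryError("all run-in stock expires before the 30-day period ends")
        # lots heap is expiry-ordered; the first eligible lot is FEFO
        lot = min(eligible, key=lambda x: x[0])
        lot[1] -= 1
        self._run_in_supplied.add(p.participant_id)
        next_due = when + timedelta(days=RUN_IN_DAYS)
        disp = Dispensation(
            participant_id=p.participant_id,
            date=when,
            step=SupplyStep.RUN_IN,
            bottle_codes=(),
            tablets_per_day=1,
            days_covered=RUN_IN_DAYS,
            next_due_date=next_due,
            product=RUN_IN_PRODUCT,
        )
        self.dispensations.append(disp)
        self.next_due[p.participant_id] = next_due
        if log is not None:
            log.record(
                "dispensation",
                p.participant_id,
                timestamp=when,
                actor_role=Role.PHARMACIST,
                step=SupplyStep.RUN_IN.value,
                product=RUN_IN_PRODUCT,
                units=1,
                days_covered=RUN_IN_DAYS,
            )
        return disp

    def _take_fefo(self, label: str, n: int, covers_until: date) -> list[str]:
        """Pop ``n`` eligible bottles FEFO, restoring everything on failure."""
        heap = self._heaps.setdefault(label, [])
        taken: list[tuple[int, str]] = []
        short_dated: list[tuple[int, str]] = []
        try:
            while len(taken) < n:
                while heap and self.bottles[heap[0][1]].status is not BottleStatus.IN_STOCK:
                    heapq.heappop(heap)  # lazily drop dispensed/disposed entries
                if not heap:
                    # popped bottles are still in stock at this point, so the
                    # dict scan counts the whole labelled stock either way
                    if self.in_stock_count(label) < n:
                        raise StockoutError(
                            f"insufficient stock of label {label}: need {n}, "
                            f"have {self.in_stock_count(label)}"
                        )
                    raise ExpiryError(
                        f"stock of label {label} cannot cover the period to "
                        f"{covers_until}: every remaining bottle is short-dated or expired"
                    )
                exp_ord, code = heapq.heappop(heap)
                if date.fromordinal(exp_ord) < covers_until:
                    short_dated.append((exp_ord, code))
                else:
                    taken.append((exp_ord, code))
        except Exception:
            for item in short_dated + taken:
                heapq.heappush(heap, item)
            raise
        for item in short_dated:  # usable for shorter future periods
            heapq.heappush(heap, item)
        return [code for _, code in taken]

    # -- disposal ----------------------------------------------------------
    def dispose_expired(self, today: date, log: Optional[AuditLog] = None) -> list[str]:
        """Dispose of every in-stock bottle (and run-in unit) past expiry."""
        disposed = []
        for code in sorted(self._in_stock):
            b = self.bottles[code]
            if b.expiry_date < today:
                b.status = BottleStatus.DISPOSED
                disposed.append(code)
        self._in_stock.difference_update(disposed)
        while self.run_in_lots and date.fromordinal(self.run_in_lots[0][0]) < today:
            heapq.heappop(self.run_in_lots)
        if disposed and log is not None:
            log.record(
                "disposal",
                "warehouse",
                timestamp=today,
                actor_role=Role.PHARMACIST,
                bottle_codes=disposed,
                count=len(disposed),
            )
        return disposed

    # -- reporting ---------------------------------------------------------
    def allocation_register(self) -> pd.DataFrame:
        """Per-participant delivery dates, bottle codes, expiries, next due."""
        rows = []
        for d in self.dispensations:
            rows.append(
                {
                    "participant_id": d.participant_id,
                    "date": str(d.date),
                    "step": d.step.value,
                    "product": d.product,
                    "bottle_codes": "|".join(d.bottle_codes),
                    "expiry_dates": "|".join(str(e) for e in d.expiry_dates),
                    "tablets_per_day": d.tablets_per_day,
                    "days_covered": d.days_covered,
                    "next_due_date": str(d.next_due_date),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "date",
                "step",
                "product",
                "bottle_codes",
                "expiry_dates",
                "tablets_per_day",
                "days_covered",
                "next_due_date",
            ],
        )

    def stock_report(self) -> pd.DataFrame:
        """Counts by blinded label, batch and status (never treatment names)."""
        rows: dict[tuple, int] = {}
        for b in self.bottles.values():
            key = (b.blinded_label, b.batch_id or "", b.status.value)
            rows[key] = rows.get(key, 0) + 1
        return pd.DataFrame(
            [
                {"blinded_label": k[0], "batch_id": k[1], "status": k[2], "count": v}
                for k, v in sorted(rows.items())
            ],
            columns=["blinded_label", "batch_id", "status", "count"],
        )

    def tablets_dispensed(self, participant_id: str) -> int:
        """Cumulative blinded tablets dispensed to one participant."""
        return sum(
            len(d.bottle_codes) * TABLETS_PER_BOTTLE
            for d in self.dispensations
            if d.participant_id == participant_id and d.product == "blinded"
        )
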