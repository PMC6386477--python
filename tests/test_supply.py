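"""Warehouse: batch loading, schedule arithmetic, FEFO, expiry guards."""

import random
from datetime import date, timedelta

import pytest

from trialkit.blinding import BottleStatus, TrialBlinding, generate_allocation_list
from trialkit.core import (
    AuditLog,
    DoseLevel,
    ParticipantState,
    TrialEvent,
    transition,
)
from trialkit.errors import ExpiryError, StateError, StockoutError, ValidationError
from trialkit.sealing import derive_key
from trialkit.supply import RUN_IN_PRODUCT, SupplyStep, Warehouse, required_supply

from conftest import make_participant

D = date(2016, 1, 1)


def make_warehouse(n_bottles=40, seed=4):
    blocks = generate_allocation_list(n_bottles, seed)
    tb = TrialBlinding.from_allocation(blocks, derive_key(seed), seed)
    return tb, Warehouse(tb.bottles)


def codes_by_label(tb, label, n):
    return [c for c, b in tb.bottles.items() if b.blinded_label == label][:n]


class TestRequiredSupply:
    @pytest.mark.parametrize(
        "step,dose,expected",
        [
            (SupplyStep.STEP_1, DoseLevel.FULL, (1, 62, 1)),
            (SupplyStep.STEP_2, DoseLevel.FULL, (1, 31, 2)),
            (SupplyStep.MAINTENANCE, DoseLevel.FULL, (6, 186, 2)),
            (SupplyStep.MAINTENANCE, DoseLevel.HALF, (3, 186, 1)),
            (SupplyStep.RUN_IN, DoseLevel.FULL, (1, 30, 1)),
        ],
    )
    def test_schedule_table(self, step, dose, expected):
        assert required_supply(step, dose) == expected

    def test_full_dose_is_1700_mg_per_day(self):
        _, days, tablets_per_day = required_supply(SupplyStep.MAINTENANCE, DoseLevel.FULL)
        assert tablets_per_day * 850 == 1700
        assert 62 * 6 == tablets_per_day * days  # six bottles last exactly 186 days

    def test_unknown_step_rejected(self):
        with pytest.raises(ValidationError):
            required_supply("weekly", DoseLevel.FULL)


class TestLoadBatch:
    def test_thirteen_month_expiry_accepted(self):
        tb, wh = make_warehouse()
        wh.load_batch("B1", "O1", D, D + timedelta(days=13 * 31), list(tb.bottles)[:8])
        assert wh.in_stock_count() == 8

    def test_eleven_month_expiry_rejected(self):
        tb, wh = make_warehouse()
        with pytest.raises(ValidationError, match="12-month"):
            wh.load_batch("B1", "O1", D, D + timedelta(days=11 * 31), list(tb.bottles)[:8])
        assert wh.in_stock_count() == 0

    def test_loading_adds_exactly_the_delivered_quantity(self):
        tb, wh = make_warehouse(124)
        wh.load_batch("B1", "O1", D, D + timedelta(days=700), list(tb.bottles))
        assert wh.in_stock_count() == 124
        assert wh.status_counts()["in_stock"] == 124

    def test_double_loading_rejected(self):
        tb, wh = make_warehouse()
        codes = list(tb.bottles)[:4]
        wh.load_batch("B1", "O1", D, D + timedelta(days=700), codes)
        with pytest.raises(ValidationError, match="already loaded"):
            wh.load_batch("B2", "O2", D, D + timedelta(days=700), codes)


def randomized_participant(label="X", dose=DoseLevel.FULL, state=ParticipantState.TREATMENT_RANDOMIZED):
    p = make_participant(state=state)
    p.treatment_label = label
    p.dose_level = dose
    p.treatment_end_date = D + timedelta(days=2000)
    return p


class TestDispense:
    def test_supply_steps_advance_the_state(self):
        tb, wh = make_warehouse(40)
        wh.load_batch("B1", "O1", D, D + timedelta(days=1500), list(tb.bottles))
        p = randomized_participant()
        d1 = wh.dispense(p, D)
        assert (p.state, d1.step, len(d1.bottle_codes)) == (
            ParticipantState.SUPPLY_STEP_1, SupplyStep.STEP_1, 1)
        d2 = wh.dispense(p, D + timedelta(days=62))
        assert (p.state, d2.step) == (ParticipantState.SUPPLY_STEP_2, SupplyStep.STEP_2)
        d3 = wh.dispense(p, D + timedelta(days=93))
        assert (p.state, len(d3.bottle_codes)) == (ParticipantState.MAINTENANCE, 6)
        assert d3.next_due_date == D + timedelta(days=93 + 186)

    def test_cumulative_tablet_schedule_closed_form(self):
        """After steps 1, 2 and k maintenance cycles: 62 + 62 + 372k tablets."""
        tb, wh = make_warehouse(80)
        wh.load_batch("B1", "O1", D, D + timedelta(days=3000), list(tb.bottles))
        p = randomized_participant()
        wh.dispense(p, D)
        wh.dispense(p, D + timedelta(days=62))
        day = 93
        for k in range(1, 5):
            wh.dispense(p, D + timedelta(days=day))
            day += 186
            assert wh.tablets_dispensed(p.participant_id) == 62 + 62 + 372 * k

    def test_half_dose_maintenance_needs_three_bottles(self):
        tb, wh = make_warehouse(40)
        wh.load_batch("B1", "O1", D, D + timedelta(days=1500), list(tb.bottles))
        p = randomized_participant(dose=DoseLevel.HALF, state=ParticipantState.SUPPLY_STEP_2)
        d = wh.dispense(p, D)
        assert len(d.bottle_codes) == 3
        assert d.tablets_per_day == 1

    def test_dispense_matches_label(self, ):
        tb, wh = make_warehouse(40)
        wh.load_batch("B1", "O1", D, D + timedelta(days=1500), list(tb.bottles))
        for label in ("X", "Y"):
            p = randomized_participant(label)
            d = wh.dispense(p, D)
            assert all(tb.bottles[c].blinded_label == label for c in d.bottle_codes)

    def test_withdrawn_participant_rejected(self):
        _, wh = make_warehouse()
        p = randomized_participant(state=ParticipantState.MAINTENANCE)
        transition(p, TrialEvent.CONSENT_WITHDRAWAL, D)
        with pytest.raises(StateError):
            wh.dispense(p, D)

    def test_blocked_participant_rejected(self):
        _, wh = make_warehouse()
        p = randomized_participant(state=ParticipantState.MAINTENANCE)
        transition(p, TrialEvent.SERIOUS_ADVERSE_EVENT, D)
        with pytest.raises(StateError):
            wh.dispense(p, D)

    def test_short_dated_stock_raises_expiry_error(self):
        """One bottle expiring in 10 days cannot cover a 31-day step."""
        tb, wh = make_warehouse(40)
        wh.min_shelf_life_months = 0  # allow a short-dated delivery for the scenario
        label = "X"
        wh.load_batch("B1", "O1", D, D + timedelta(days=10), codes_by_label(tb, label, 1))
        p = randomized_participant(label, state=ParticipantState.SUPPLY_STEP_1)
        with pytest.raises(ExpiryError):
            wh.dispense(p, D)

    def test_stockout_distinct_from_expiry(self):
        tb, wh = make_warehouse(40)
        p = randomized_participant("X")
        with pytest.raises(StockoutError):
            wh.dispense(p, D)

    def test_failed_dispense_leaves_stock_untouched(self):
        tb, wh = make_warehouse(40)
        wh.min_shelf_life_months = 0
        label = "Y"
        wh.load_batch("B1", "O1", D, D + timedelta(days=40), codes_by_label(tb, label, 3))
        p = randomized_participant(label, state=ParticipantState.SUPPLY_STEP_2)
        with pytest.raises(StockoutError):
            wh.dispense(p, D)  # needs 6 bottles, only 3 exist
        assert wh.in_stock_count(label) == 3
        q = randomized_participant(label, state=ParticipantState.SUPPLY_STEP_1)
        d = wh.dispense(q, D)  # 31-day coverage is still possible
        assert len(d.bottle_codes) == 1

    def test_fefo_takes_earliest_eligible_expiry(self):
        tb, wh = make_warehouse(40)
        label = "X"
        codes = codes_by_label(tb, label, 4)
        for i, c in enumerate(codes):
            wh.load_batch(f"B{i}", "O1", D, D + timedelta(days=400 + 100 * i), [c])
        p = randomized_participant(label)
        d = wh.dispense(p, D)  # step 1, one bottle
        assert d.bottle_codes == (codes[0],)

    def test_fefo_skips_short_dated_without_consuming(self):
        tb, wh = make_warehouse(40)
        wh.min_shelf_life_months = 0
        label = "X"
        codes = codes_by_label(tb, label, 3)
        wh.load_batch("B0", "O1", D, D + timedelta(days=20), [codes[0]])  # too short for 62 d
        wh.load_batch("B1", "O1", D, D + timedelta(days=500), codes[1:])
        p = randomized_participant(label)
        d = wh.dispense(p, D)
        assert d.bottle_codes == (codes[1],)
        assert wh.bottles[codes[0]].status is BottleStatus.IN_STOCK

    def test_fefo_property_randomized_scenarios(self):
        """Dispensed bottles are never later-expiring than eligible leftovers."""
        rng = random.Random(0)
        for trial_i in range(20):
            tb, wh = make_warehouse(96, seed=trial_i)
            codes = list(tb.bottles)
            rng.shuffle(codes)
            for j in range(0, 96, 8):
                wh.load_batch(
                    f"B{j}", "O", D,
                    D + timedelta(days=rng.randrange(380, 1200)), codes[j:j + 8],
                )
            for k in range(10):
                state = rng.choice(
                    [ParticipantState.TREATMENT_RANDOMIZED, ParticipantState.SUPPLY_STEP_1,
                     ParticipantState.SUPPLY_STEP_2, ParticipantState.MAINTENANCE]
                )
                p = randomized_participant(rng.choice("XY"), state=state)
                p.participant_id = f"P{trial_i}_{k}"
                when = D + timedelta(days=rng.randrange(0, 200))
                try:
                    d = wh.dispense(p, when)
                except (StockoutError, ExpiryError):
                    continue
                covers = when + timedelta(days=d.days_covered)
                leftovers = [
                    wh.bottles[c].expiry_date
                    for c in wh._in_stock
                    if wh.bottles[c].blinded_label == p.treatment_label
                    and wh.bottles[c].expiry_date >= covers
                ]
                if leftovers:
                    assert max(d.expiry_dates) <= min(leftovers)


class TestRunIn:
    def test_run_in_uses_open_label_stock(self):
        _, wh = make_warehouse()
        wh.load_run_in_lot("R1", D, D + timedelta(days=800), 5)
        p = make_participant(state=ParticipantState.RUN_IN)
        d = wh.dispense(p, D)
        assert d.product == RUN_IN_PRODUCT
        assert d.bottle_codes == ()
        assert wh.run_in_units() == 4
        with pytest.raises(StateError, match="already received"):
            wh.dispense(p, D)

    def test_run_in_stockout(self):
        _, wh = make_warehouse()
        p = make_participant(state=ParticipantState.RUN_IN)
        with pytest.raises(StockoutError):
            wh.dispense(p, D)


class TestDisposal:
    def test_no_expired_stock_is_a_noop(self):
        tb, wh = make_warehouse()
        wh.load_batch("B1", "O1", D, D + timedelta(days=700), list(tb.bottles)[:8])
        assert wh.dispose_expired(D + timedelta(days=10)) == []

    def test_expired_bottles_disposed_and_conserved(self):
        tb, wh = make_warehouse(100)
        codes = list(tb.bottles)
        wh.load_batch("B1", "O1", D, D + timedelta(days=400), codes[:7])
        wh.load_batch("B2", "O1", D, D + timedelta(days=900), codes[7:100])
        disposed = wh.dispose_expired(D + timedelta(days=500))
        assert len(disposed) == 7
        assert wh.in_stock_count() == 93
        counts = wh.status_counts()
        assert counts["disposed"] == 7 and counts["in_stock"] == 93

    def test_disposed_bottles_cannot_be_dispensed(self):
        tb, wh = make_warehouse(8)
        wh.load_batch("B1", "O1", D, D + timedelta(days=400), list(tb.bottles))
        wh.dispose_expired(D + timedelta(days=500))
        p = randomized_participant("X")
        with pytest.raises(StockoutError):
            wh.dispense(p, D + timedelta(days=500))


class TestRegister:
    def test_register_rows_and_conservation(self):
        tb, wh = make_warehouse(80)
        log = AuditLog()
        wh.load_batch("B1", "O1", D, D + timedelta(days=3000), list(tb.bottles), log)
        p = randomized_participant()
        wh.dispense(p, D, log)
        wh.dispense(p, D + timedelta(days=62), log)
        wh.dispense(p, D + timedelta(days=93), log)
        reg = wh.allocation_register()
        mine = reg[reg.participant_id == p.participant_id]
        assert len(mine) == 3
        total_codes = sum(len(c.split("|")) for c in mine.bottle_codes if c)
        assert total_codes == wh.status_counts()["dispensed"] == 8
        assert mine.iloc[-1].next_due_date == str(D + timedelta(days=93 + 186))

    def test_register_and_stock_report_never_name_treatments(self):
        tb, wh = make_warehouse(40)
        wh.load_batch("B1", "O1", D, D + timedelta(days=1500), list(tb.bottles))
        p = randomized_participant()
        wh.dispense(p, D)
        text = wh.allocation_register().to_csv() + wh.stock_report().to_csv()
        assert "metformin" not in text.lower()
        assert "placebo" not in text.lower()
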