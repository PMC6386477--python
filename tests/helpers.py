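"""Shared verification helpers: cross-module invariants and oracles."""

from __future__ import annotations

from datetime import date, timedelta

from trialkit.core import RANDOMIZED_STATES, ParticipantState
from trialkit.supply import SupplyStep


def verify_conservation(result) -> None:
    """Generated = not-yet-loaded + in stock + dispensed + disposed."""
    counts = result.bottle_status_counts
    assert sum(counts.values()) == result.config.allocation_bottles
    loaded = sum(len(b.codes) for b in result.trial.warehouse.batches.values())
    assert loaded == counts["in_stock"] + counts["dispensed"] + counts["disposed"]
    assert counts["dispensed"] == result.dispensed_bottles


def verify_no_expired_dispensing(result) -> None:
    """Every blinded dispensation is covered by all its bottles' expiries."""
    for d in result.trial.warehouse.dispensations:
        if d.product != "blinded":
            continue
        assert d.bottle_codes, d
        assert min(d.expiry_dates) >= d.date + timedelta(days=d.days_covered), d


def verify_fefo(trial) -> None:
    """Replay loads and dispensations: every dispensation took the
    earliest-expiring eligible bottles of its label available at the time."""
    events = []
    for b in trial.warehouse.batches.values():
        for code in b.codes:
            events.append((b.load_date, 0, 0, ("load", code, b.expiry_date)))
    for seq, d in enumerate(trial.warehouse.dispensations):
        if d.product == "blinded":
            events.append((d.date, 1, seq, ("disp", d)))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    stock: dict[str, dict[str, date]] = {}  # label -> {code: expiry}
    for _, _, _, ev in events:
        if ev[0] == "load":
            code, expiry = ev[1], ev[2]
            label = trial.blinding.bottles[code].blinded_label
            stock.setdefault(label, {})[code] = expiry
        else:
            d = ev[1]
            label = trial.blinding.bottles[d.bottle_codes[0]].blinded_label
            covers = d.date + timedelta(days=d.days_covered)
            pool = stock[label]
            for code in d.bottle_codes:
                assert code in pool, f"dispensed bottle {code} not in replayed stock"
                del pool[code]
            remaining_eligible = [e for e in pool.values() if e >= covers]
            if remaining_eligible:
                assert max(d.expiry_dates) <= min(remaining_eligible), (
                    f"FEFO violated at {d.date} for {d.participant_id}"
                )


def brute_force_A(trial, today: date, horizon_months: int) -> int:
    """Independent day-by-day enumeration of bottles due within the horizon.

    Walks each randomized active participant's calendar one day at a time
    with the schedule constants written out literally.
    """
    first_step = {
        ParticipantState.TREATMENT_RANDOMIZED: "step_1",
        ParticipantState.SUPPLY_STEP_1: "step_2",
        ParticipantState.SUPPLY_STEP_2: "maintenance",
        ParticipantState.MAINTENANCE: "maintenance",
    }
    window_end = today + timedelta(days=horizon_months * 31)
    total = 0
    for p in trial.participants.values():
        if p.state not in RANDOMIZED_STATES or p.treatment_end_date is None:
            continue
        supplies = {
            "step_1": (1, 62),
            "step_2": (1, 31),
            "maintenance": (6, 186) if p.dose_level.value == "full" else (3, 186),
        }
        after = {"step_1": "step_2", "step_2": "maintenance", "maintenance": "maintenance"}
        step = first_step[p.state]
        due = trial.warehouse.next_due.get(p.participant_id, today)
        day = min(due, today)
        while day < window_end:
            if day == due and day < p.treatment_end_date:
                n, days = supplies[step]
                if day >= today:
                    total += n
                due = day + timedelta(days=days)
                step = after[step]
            day += timedelta(days=1)
    return total


def operational_output_closure(result, sample_bottles: int = 200) -> str:
    """Concatenated operational (blinded) outputs of a simulated trial.

    Everything a data manager or pharmacist can see: the participant-facing
    balance table, the allocation register, the stock report, a sample of
    operational bottle views, and the audit log minus the unblinding
    payloads (which are the PI's decrypted view by design).
    """
    trial = result.trial
    parts = [
        result.balance.table.to_csv(),
        trial.warehouse.allocation_register().to_csv(index=False),
        trial.warehouse.stock_report().to_csv(index=False),
        result.to_json(),
    ]
    for code in list(trial.blinding.bottles)[:sample_bottles]:
        parts.append(str(trial.blinding.operational_view(code)))
    for e in trial.audit:
        if e.action == "unblinding":
            parts.append(e.action + e.subject)  # payload deliberately excluded
        else:
            parts.append(e.to_json())
    return "\n".join(parts)


def assert_blind_integrity(text: str) -> None:
    low = text.lower()
    assert "metformin" not in low
    assert "placebo" not in low
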