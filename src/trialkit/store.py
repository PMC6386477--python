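"""On-disk trial bundle (plain CSV/JSON/JSONL) and reference fixtures.

The bundle is a directory of diffable text files: ``participants.csv``,
``bottles.csv``, ``batches.csv``, ``run_in_lots.csv``, ``register.csv``,
``ledger.json``, ``config.json``, ``audit.jsonl`` and ``sealed_map.json``
(the encrypted treatment map, base64).  The unblinding key is *not* part
of the bundle; it is supplied at unblinding time.  ``load(save(state))``
is the identity on everything observable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd

from .blinding import Bottle, BottleStatus, TrialBlinding
from .core import AuditLog, DietArm, DoseLevel, Participant, ParticipantState, Sex
from .errors import ValidationError
from .supply import Batch, Dispensation, RunInLot, SupplyStep, Warehouse
from .trial import Trial

_FILES = (
    "participants.csv",
    "bottles.csv",
    "batches.csv",
    "run_in_lots.csv",
    "register.csv",
    "ledger.json",
    "config.json",
    "audit.jsonl",
    "sealed_map.json",
)


def _opt(v) -> str:
    return "" if v is None else str(v)


def _opt_date(s) -> Optional[date]:
    s = "" if s is None else str(s)
    return date.fromisoformat(s) if s else None


def save_trial(trial: Trial, path) -> Path:
    """Write the trial bundle; deterministic column and row order."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    rows = []
    for pid in sorted(trial.participants):
        p = trial.participants[pid]
        rows.append(
            {
                "participant_id": p.participant_id,
                "sex": p.sex.value,
                "birth_date": str(p.birth_date),
                "consent_date": str(p.consent_date),
                "family_id": _opt(p.family_id),
                "is_proband": int(p.is_proband),
                "state": p.state.value,
                "diet_arm": _opt(p.diet_arm.value if p.diet_arm else None),
                "treatment_label": _opt(p.treatment_label),
                "dose_level": p.dose_level.value,
                "anniversary_date": _opt(p.anniversary_date),
                "randomization_date": _opt(p.randomization_date),
                "treatment_end_date": _opt(p.treatment_end_date),
            }
        )
    pcols = [
        "participant_id", "sex", "birth_date", "consent_date", "family_id",
        "is_proband", "state", "diet_arm", "treatment_label", "dose_level",
        "anniversary_date", "randomization_date", "treatment_end_date",
    ]
    pd.DataFrame(rows, columns=pcols).to_csv(root / "participants.csv", index=False)

    brows = []
    for code in sorted(trial.blinding.bottles) if trial.blinding else []:
        b = trial.blinding.bottles[code]
        brows.append(
            {
                "code": b.code,
                "block_id": b.block_id,
                "position_in_block": b.position_in_block,
                "blinded_label": b.blinded_label,
                "status": b.status.value,
                "batch_id": _opt(b.batch_id),
                "expiry_date": _opt(b.expiry_date),
            }
        )
    bcols = ["code", "block_id", "position_in_block", "blinded_label",
             "status", "batch_id", "expiry_date"]
    pd.DataFrame(brows, columns=bcols).to_csv(root / "bottles.csv", index=False)

    wh = trial.warehouse
    pd.DataFrame(
        [
            {
                "batch_id": b.batch_id,
                "order_id": b.order_id,
                "load_date": str(b.load_date),
                "expiry_date": str(b.expiry_date),
            }
            for b in (wh.batches[k] for k in sorted(wh.batches))
        ],
        columns=["batch_id", "order_id", "load_date", "expiry_date"],
    ).to_csv(root / "batches.csv", index=False)

    remaining = {lot[2]: lot[1] for lot in wh.run_in_lots}
    pd.DataFrame(
        [
            {
                "lot_id": lot.lot_id,
                "load_date": str(lot.load_date),
                "expiry_date": str(lot.expiry_date),
                "units_loaded": lot.units,
                "units_remaining": remaining.get(lot.lot_id, 0),
            }
            for lot in wh.run_in_history
        ],
        columns=["lot_id", "load_date", "expiry_date", "units_loaded", "units_remaining"],
    ).to_csv(root / "run_in_lots.csv", index=False)

    wh.allocation_register().to_csv(root / "register.csv", index=False)

    ledger = trial.ledger
    (root / "ledger.json").write_text(
        json.dumps(
            {
                "diet_sex": {f"{k[0]}|{k[1]}": v for k, v in sorted(ledger.diet_sex.items())},
                "treatment_sex": {
                    f"{k[0]}|{k[1]}": v for k, v in sorted(ledger.treatment_sex.items())
                },
                "treatment_age": {
                    f"{k[0]}|{k[1]}": v for k, v in sorted(ledger.treatment_age.items())
                },
                "family_arms": {k: v.value for k, v in sorted(ledger.family_arms.items())},
                "treatment_dates": [str(d) for d in ledger.treatment_dates],
                "next_due": {k: str(v) for k, v in sorted(wh.next_due.items())},
            },
            indent=1,
            sort_keys=True,
        )
    )

    def _rng_state(r):
        st = r.getstate()
        return [st[0], list(st[1]), st[2]]

    (root / "config.json").write_text(
        json.dumps(
            {
                "seed": trial.seed,
                "min_shelf_life_months": wh.min_shelf_life_months,
                "rng_diet": _rng_state(trial.rng_diet),
                "rng_treatment": _rng_state(trial.rng_treatment),
            },
            indent=1,
        )
    )
    (root / "audit.jsonl").write_text(trial.audit.to_jsonl())
    (root / "sealed_map.json").write_text(
        json.dumps(
            {"version": 1, "sealed": trial.blinding.sealed_map if trial.blinding else None}
        )
    )
    return root


def load_trial(path, key: Optional[bytes] = None) -> Trial:
    """Reconstruct a trial from a bundle written by :func:`save_trial`."""
    root = Path(path)
    for name in _FILES:
        if not (root / name).exists():
            raise ValidationError(f"not a trial store: missing {name}")
    config = json.loads((root / "config.json").read_text())
    trial = Trial(seed=config["seed"], key=key)

    def _set_state(r, st):
        r.setstate((st[0], tuple(st[1]), st[2]))

    _set_state(trial.rng_diet, config["rng_diet"])
    _set_state(trial.rng_treatment, config["rng_treatment"])

    sealed = json.loads((root / "sealed_map.json").read_text())["sealed"]
    bdf = pd.read_csv(root / "bottles.csv", dtype=str, keep_default_na=False)
    bottles: dict[str, Bottle] = {}
    for r in bdf.itertuples(index=False):
        bottles[r.code] = Bottle(
            code=r.code,
            block_id=int(r.block_id),
            position_in_block=int(r.position_in_block),
            blinded_label=r.blinded_label,
            status=BottleStatus(r.status),
            batch_id=r.batch_id or None,
            expiry_date=_opt_date(r.expiry_date),
        )
    if sealed is not None:
        trial.blinding = TrialBlinding(bottles=bottles, sealed_map=sealed)
    wh = Warehouse(bottles, min_shelf_life_months=config["min_shelf_life_months"])
    trial.warehouse = wh
    for code, b in bottles.items():
        if b.status is BottleStatus.IN_STOCK:
            import heapq

            heapq.heappush(
                wh._heaps.setdefault(b.blinded_label, []), (b.expiry_date.toordinal(), code)
            )
            wh._in_stock.add(code)

    pdf = pd.read_csv(root / "participants.csv", dtype=str, keep_default_na=False)
    for r in pdf.itertuples(index=False):
        trial.participants[r.participant_id] = Participant(
            participant_id=r.participant_id,
            sex=Sex(r.sex),
            birth_date=date.fromisoformat(r.birth_date),
            consent_date=date.fromisoformat(r.consent_date),
            family_id=r.family_id or None,
            is_proband=bool(int(r.is_proband)),
            state=ParticipantState(r.state),
            diet_arm=DietArm(r.diet_arm) if r.diet_arm else None,
            treatment_label=r.treatment_label or None,
            dose_level=DoseLevel(r.dose_level),
            anniversary_date=_opt_date(r.anniversary_date),
            randomization_date=_opt_date(r.randomization_date),
            treatment_end_date=_opt_date(r.treatment_end_date),
        )

    batch_codes: dict[str, list[str]] = {}
    for code, b in bottles.items():
        if b.batch_id:
            batch_codes.setdefault(b.batch_id, []).append(code)
    batdf = pd.read_csv(root / "batches.csv", dtype=str, keep_default_na=False)
    for r in batdf.itertuples(index=False):
        wh.batches[r.batch_id] = Batch(
            batch_id=r.batch_id,
            order_id=r.order_id,
            load_date=date.fromisoformat(r.load_date),
            expiry_date=date.fromisoformat(r.expiry_date),
            codes=tuple(sorted(batch_codes.get(r.batch_id, []))),
        )

    import heapq

    ldf = pd.read_csv(root / "run_in_lots.csv", dtype=str, keep_default_na=False)
    for r in ldf.itertuples(index=False):
        lot = RunInLot(
            lot_id=r.lot_id,
            load_date=date.fromisoformat(r.load_date),
            expiry_date=date.fromisoformat(r.expiry_date),
            units=int(r.units_loaded),
        )
        wh.run_in_history.append(lot)
        if int(r.units_remaining) > 0:
            heapq.heappush(
                wh.run_in_lots,
                [lot.expiry_date.toordinal(), int(r.units_remaining), lot.lot_id],
            )

    rdf = pd.read_csv(root / "register.csv", dtype=str, keep_default_na=False)
    for r in rdf.itertuples(index=False):
        codes = tuple(c for c in r.bottle_codes.split("|") if c)
        expiries = tuple(date.fromisoformat(e) for e in r.expiry_dates.split("|") if e)
        wh.dispensations.append(
            Dispensation(
                participant_id=r.participant_id,
                date=date.fromisoformat(r.date),
                step=SupplyStep(r.step),
                bottle_codes=codes,
                tablets_per_day=int(r.tablets_per_day),
                days_covered=int(r.days_covered),
                next_due_date=date.fromisoformat(r.next_due_date),
                expiry_dates=expiries,
                product=r.product,
            )
        )
        if r.step == SupplyStep.RUN_IN.value:
            wh._run_in_supplied.add(r.participant_id)

    ledger = json.loads((root / "ledger.json").read_text())

    def _unkey(d):
        return {tuple(k.split("|")): v for k, v in d.items()}

    trial.ledger.diet_sex = _unkey(ledger["diet_sex"])
    trial.ledger.treatment_sex = _unkey(ledger["treatment_sex"])
    trial.ledger.treatment_age = _unkey(ledger["treatment_age"])
    trial.ledger.family_arms = {k: DietArm(v) for k, v in ledger["family_arms"].items()}
    trial.ledger.treatment_dates = [date.fromisoformat(d) for d in ledger["treatment_dates"]]
    wh.next_due = {k: date.fromisoformat(v) for k, v in ledger["next_due"].items()}

    trial.audit = AuditLog.from_jsonl((root / "audit.jsonl").read_text())
    return trial


def snapshot(trial: Trial) -> dict:
    """Canonical observable state, for round-trip and replay checks."""
    return {
        "participants": {
            pid: {
                "state": p.state.value,
                "sex": p.sex.value,
                "diet_arm": p.diet_arm.value if p.diet_arm else None,
                "treatment_label": p.treatment_label,
                "dose_level": p.dose_level.value,
                "family_id": p.family_id,
                "is_proband": p.is_proband,
            }
            for pid, p in sorted(trial.participants.items())
        },
        "bottle_status": (
            {c: b.status.value for c, b in sorted(trial.blinding.bottles.items())}
            if trial.blinding
            else {}
        ),
        "next_due": {k: str(v) for k, v in sorted(trial.warehouse.next_due.items())},
        "dispensations": len(trial.warehouse.dispensations),
        "audit": trial.audit.to_jsonl(),
        "diet_sex": {f"{a}|{b}": v for (a, b), v in sorted(trial.ledger.diet_sex.items())},
        "treatment_sex": {
            f"{a}|{b}": v for (a, b), v in sorted(trial.ledger.treatment_sex.items())
        },
    }


# --------------------------------------------------------------------------
# Reference balance table fixture
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Fixture:
    """The published diet-randomization balance counts.

    Cells are (role, arm, sex) -> count; marginals are derived on demand.
    """

    cells: dict

    def row_total(self, role: str) -> int:
        return sum(v for (r, _, _), v in self.cells.items() if r == role)

    @property
    def proband_total(self) -> int:
        return self.row_total("proband")

    @property
    def familiar_total(self) -> int:
        return self.row_total("familiar")

    @property
    def grand_total(self) -> int:
        return self.proband_total + self.familiar_total

    def arm_total(self, arm: str, role: Optional[str] = None) -> int:
        return sum(
            v
            for (r, a, _), v in self.cells.items()
            if a == arm and (role is None or r == role)
        )

    def to_participants(self) -> list[Participant]:
        """Synthesize a roster reproducing the printed cells exactly.

        Familiars are attached one-per-family to probands of the same arm,
        so family consistency holds by construction.
        """
        out: list[Participant] = []
        proband_ids: dict[str, list[str]] = {"blue": [], "green": []}
        n = 0
        birth, consent = date(1960, 1, 1), date(2016, 1, 1)
        for (role, arm, sex), count in sorted(self.cells.items()):
            if role != "proband":
                continue
            for _ in range(count):
                n += 1
                pid = f"T{n:05d}"
                out.append(
                    Participant(
                        participant_id=pid,
                        sex=Sex(sex),
                        birth_date=birth,
                        consent_date=consent,
                        state=ParticipantState.DIET_RANDOMIZED,
                        diet_arm=DietArm(arm),
                        is_proband=True,
                    )
                )
                proband_ids[arm].append(pid)
        used = {"blue": 0, "green": 0}
        for (role, arm, sex), count in sorted(self.cells.items()):
            if role != "familiar":
                continue
            for _ in range(count):
                n += 1
                host = proband_ids[arm][used[arm]]
                used[arm] += 1
                fid = f"F{host}"
                for p in out:
                    if p.participant_id == host:
                        p.family_id = fid
                        break
                out.append(
                    Participant(
                        participant_id=f"T{n:05d}",
                        sex=Sex(sex),
                        birth_date=birth,
                        consent_date=consent,
                        state=ParticipantState.DIET_RANDOMIZED,
                        diet_arm=DietArm(arm),
                        is_proband=False,
                        family_id=fid,
                    )
                )
        return out


def load_table1_fixture() -> Table1Fixture:
    """The published proband/familiar x arm x sex balance table."""
    return Table1Fixture(
        cells={
            ("proband", "blue", "male"): 327,
            ("proband", "blue", "female"): 479,
            ("proband", "green", "male"): 349,
            ("proband", "green", "female"): 456,
            ("familiar", "blue", "male"): 13,
            ("familiar", "blue", "female"): 68,
            ("familiar", "green", "male"): 5,
            ("familiar", "green", "female"): 58,
        }
    )
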