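"""Blinded bottle allocation, manufacturer export and emergency unblinding.

The allocation list is generated once per trial, in randomized blocks of
four bottles (two metformin, two placebo) so the cumulative treatment ratio
after whole blocks is exactly 1:1.  The plaintext list exists only at
generation time: one copy is exported for the drug manufacturer (bottle
code and treatment name, nothing else), and the in-database copy is sealed
under key.  Operationally every bottle shows only its blinded label (X or
Y); the X/Y-to-treatment mapping is itself drawn at random from the master
seed and then sealed.  Only the PI can break the blind, and every
decryption is audited.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .core import AuditEvent, AuditLog, Participant, Role
from .errors import AuthorizationError, StateError, UnknownCodeError, ValidationError
from . import sealing

TREATMENTS = ("metformin", "placebo")
BLOCK_SIZE = 4  # two bottles of each treatment per block
TABLETS_PER_BOTTLE = 62

_CHECK_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ*"  # 37 symbols


class BottleStatus(str, Enum):
    GENERATED = "generated"  # on the allocation list, not yet delivered
    IN_STOCK = "in_stock"  # loaded from a batch into the virtual warehouse
    DISPENSED = "dispensed"
    DISPOSED = "disposed"


def checksum_char(digits: str) -> str:
    """Position-weighted mod-37 check character for a numeric code body.

    37 is prime and exceeds every weight x digit-delta product that a
    single-digit substitution can produce, so any such error is caught.
    """
    total = sum((i + 1) * int(d) for i, d in enumerate(digits))
    return _CHECK_ALPHABET[total % 37]


def make_code(number: int) -> str:
    body = f"{number:07d}"
    return body + checksum_char(body)


def validate_code(code: str) -> bool:
    body, check = code[:-1], code[-1:]
    return body.isdigit() and checksum_char(body) == check


@dataclass(slots=True)
class Bottle:
    """Operational (blinded) view of one 62-tablet kit unit."""

    code: str
    block_id: int
    position_in_block: int  # 1..4
    blinded_label: str  # X or Y; the treatment lives only in the sealed map
    status: BottleStatus = BottleStatus.GENERATED
    batch_id: Optional[str] = None
    expiry_date: Optional[date] = None


@dataclass(frozen=True)
class AllocationBlock:
    """Design-time block: four bottle codes with their treatments."""

    block_id: int
    codes: tuple[str, str, str, str]
    treatments: tuple[str, str, str, str]


def generate_allocation_list(n_bottles: int, seed: int) -> list[AllocationBlock]:
    """Generate ``n_bottles / 4`` randomized blocks, reproducibly from seed.

    Each block is a random permutation of two metformin and two placebo
    bottles; codes are unique zero-padded integers with a check character.
    """
    if n_bottles < BLOCK_SIZE or n_bottles % BLOCK_SIZE != 0:
        raise ValidationError(
            f"n_bottles must be a positive multiple of {BLOCK_SIZE}, got {n_bottles}"
        )
    rng = random.Random(seed)
    blocks = []
    number = 1
    base = (TREATMENTS[0], TREATMENTS[0], TREATMENTS[1], TREATMENTS[1])
    for block_id in range(1, n_bottles // BLOCK_SIZE + 1):
        treatments = list(base)
        rng.shuffle(treatments)
        codes = tuple(make_code(number + i) for i in range(BLOCK_SIZE))
        number += BLOCK_SIZE
        blocks.append(AllocationBlock(block_id=block_id, codes=codes, treatments=tuple(treatments)))
    return blocks


def export_manufacturer_list(blocks: Iterable[AllocationBlock]) -> pd.DataFrame:
    """Plaintext packaging instructions for the supplier.

    Bottle code and treatment name are the sole columns; the schema has no
    participant field, so the export can never tie a treatment to a person.
    """
    rows = [
        {"bottle_code": c, "treatment": t}
        for b in blocks
        for c, t in zip(b.codes, b.treatments)
    ]
    return pd.DataFrame(rows, columns=["bottle_code", "treatment"])


class TrialBlinding:
    """Sealed double-blind state: blinded bottles plus the encrypted map."""

    def __init__(self, bottles: dict[str, Bottle], sealed_map: str) -> None:
        self.bottles = bottles
        self.sealed_map = sealed_map  # base64 token; decrypt only via break_blind

    @classmethod
    def from_allocation(
        cls, blocks: Iterable[AllocationBlock], key: bytes, seed: int
    ) -> "TrialBlinding":
        """Seal a freshly generated allocation list.

        The X/Y aliases are themselves assigned to the two treatments at
        random from ``seed``, so the labels carry no information.
        """
        rng = random.Random((int(seed) ^ 0x5EA1) & 0x7FFFFFFF)
        shuffled = list(TREATMENTS)
        rng.shuffle(shuffled)
        label_map = {"X": shuffled[0], "Y": shuffled[1]}
        label_of = {t: lab for lab, t in label_map.items()}
        bottles: dict[str, Bottle] = {}
        bottle_treatments: dict[str, str] = {}
        for b in blocks:
            for pos, (code, treatment) in enumerate(zip(b.codes, b.treatments), start=1):
                bottles[code] = Bottle(
                    code=code,
                    block_id=b.block_id,
                    position_in_block=pos,
                    blinded_label=label_of[treatment],
                )
                bottle_treatments[code] = treatment
        nonce = sealing.derive_key(int(seed) + 7)[:16]
        sealed = sealing.seal_json(
            key, {"labels": label_map, "bottles": bottle_treatments}, nonce=nonce
        )
        return cls(bottles=bottles, sealed_map=sealed)

    # -- operational (blinded) queries ------------------------------------
    def operational_view(self, code: str) -> dict:
        """Blinded record for one bottle: code, block, status, label only."""
        if code not in self.bottles:
            raise UnknownCodeError(f"unknown bottle code: {code}")
        b = self.bottles[code]
        return {
            "code": b.code,
            "block_id": b.block_id,
            "position_in_block": b.position_in_block,
            "status": b.status.value,
            "blinded_label": b.blinded_label,
            "batch_id": b.batch_id,
            "expiry_date": str(b.expiry_date) if b.expiry_date else None,
        }

    # -- emergency unblinding ---------------------------------------------
    def break_blind(
        self,
        participant: Participant,
        *,
        actor_id: str,
        actor_role: Role,
        reason: str,
        key: bytes,
        when,
        log: Optional[AuditLog] = None,
    ) -> tuple[str, AuditEvent]:
        """Decrypt a participant's treatment.  PI only; fully audited."""
        if Role(actor_role) is not Role.PI:
            raise AuthorizationError(
                f"breaking the blind is restricted to the PI; actor role was "
                f"'{Role(actor_role).value}'"
            )
        if not reason or not reason.strip():
            raise ValidationError("a non-empty reason is required to break the blind")
        if participant.treatment_label is None:
            raise StateError(
                f"participant {participant.participant_id} has no blinded "
                f"assignment yet (state {participant.state.value})"
            )
        mapping = sealing.unseal_json(key, self.sealed_map)
        treatment = mapping["labels"][participant.treatment_label]
        audit = AuditEvent(
            timestamp=str(when),
            actor_id=actor_id,
            actor_role=Role.PI,
            action="unblinding",
            subject=participant.participant_id,
            payload={"reason": reason, "treatment": treatment},
        )
        if log is not None:
            log.append(audit)
        return treatment, audit

    def unblind_bottle(
        self,
        code: str,
        *,
        actor_id: str,
        actor_role: Role,
        reason: str,
        key: bytes,
        when,
        log: Optional[AuditLog] = None,
    ) -> tuple[str, AuditEvent]:
        """Decrypt one bottle's treatment from the sealed per-bottle table."""
        if Role(actor_role) is not Role.PI:
            raise AuthorizationError("breaking the blind is restricted to the PI")
        if not reason or not reason.strip():
            raise ValidationError("a non-empty reason is required to break the blind")
        if code not in self.bottles:
            raise UnknownCodeError(f"unknown bottle code: {code}")
        mapping = sealing.unseal_json(key, self.sealed_map)
        treatment = mapping["bottles"][code]
        audit = AuditEvent(
            timestamp=str(when),
            actor_id=actor_id,
            actor_role=Role.PI,
            action="unblinding",
            subject=code,
            payload={"reason": reason, "treatment": treatment},
        )
        if log is not None:
            log.append(audit)
        return treatment, audit
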