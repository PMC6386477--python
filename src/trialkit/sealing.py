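"""Authenticated symmetric sealing for the treatment map.

A compact encrypt-then-MAC construction on top of the standard library:
the keystream is HMAC-SHA256 in counter mode under an encryption subkey,
and the tag is HMAC-SHA256 over nonce and ciphertext under a separate
authentication subkey (both derived from the trial key).  Decryption fails
closed on any tampering or wrong key.

This protects the blind inside the operational store; it is not intended
as a general-purpose cryptographic library.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import secrets

from .errors import SealError

_NONCE_BYTES = 16
_TAG_BYTES = 32
_BLOCK = hashlib.sha256().digest_size


def _subkeys(key: bytes) -> tuple[bytes, bytes]:
    enc = hmac.new(key, b"trialkit-seal-enc", hashlib.sha256).digest()
    mac = hmac.new(key, b"trialkit-seal-mac", hashlib.sha256).digest()
    return enc, mac


def _keystream(enc_key: bytes, nonce: bytes, n: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < n:
        out += hmac.new(enc_key, nonce + counter.to_bytes(8, "big"), hashlib.sha256).digest()
        counter += 1
    return bytes(out[:n])


def seal(key: bytes, plaintext: bytes, *, nonce: bytes | None = None) -> bytes:
    """Encrypt and authenticate ``plaintext``; returns nonce || ct || tag."""
    if nonce is None:
        nonce = secrets.token_bytes(_NONCE_BYTES)
    if len(nonce) != _NONCE_BYTES:
        raise SealError(f"nonce must be {_NONCE_BYTES} bytes")
    enc_key, mac_key = _subkeys(key)
    ct = bytes(a ^ b for a, b in zip(plaintext, _keystream(enc_key, nonce, len(plaintext))))
    tag = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    return nonce + ct + tag


def unseal(key: bytes, token: bytes) -> bytes:
    """Verify and decrypt a sealed token; raises :class:`SealError` on failure."""
    if len(token) < _NONCE_BYTES + _TAG_BYTES:
        raise SealError("sealed token too short")
    nonce, ct, tag = (
        token[:_NONCE_BYTES],
        token[_NONCE_BYTES:-_TAG_BYTES],
        token[-_TAG_BYTES:],
    )
    enc_key, mac_key = _subkeys(key)
    expect = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expect):
        raise SealError("authentication failed: wrong key or tampered token")
    return bytes(a ^ b for a, b in zip(ct, _keystream(enc_key, nonce, len(ct))))


def seal_json(key: bytes, obj, *, nonce: bytes | None = None) -> str:
    """Seal a JSON-serializable object to a base64 text token."""
    raw = seal(key, json.dumps(obj, sort_keys=True).encode(), nonce=nonce)
    return base64.b64encode(raw).decode("ascii")


def unseal_json(key: bytes, token: str):
    return json.loads(unseal(key, base64.b64decode(token.encode("ascii"))))


def derive_key(seed: int) -> bytes:
    """Deterministic trial key from a master seed (for simulations/tests)."""
    return hashlib.sha256(b"trialkit-key-" + str(int(seed)).encode()).digest()
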