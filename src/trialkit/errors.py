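"""Exception hierarchy shared by every module.

All domain failures derive from :class:`TrialError` so callers (and the CLI)
can distinguish domain errors (exit code 1) from usage errors (exit code 2).
"""


class TrialError(Exception):
    """Base class for every domain-level failure."""


class ValidationError(TrialError):
    """Malformed or missing input data; the message names the field."""


class StateError(TrialError):
    """An operation that is illegal in the participant's current state."""


class GatingError(TrialError):
    """A randomization precondition is not met; the message names the gap."""


class AuthorizationError(TrialError):
    """The acting role is not allowed to perform the operation."""


class UnknownCodeError(TrialError):
    """Lookup of a bottle code, batch or participant that does not exist."""


class StockoutError(TrialError):
    """Not enough bottles of the required blinded label in stock."""


class ExpiryError(TrialError):
    """Stock exists but every eligible bottle is too close to expiry."""


class SealError(TrialError):
    """The sealed treatment map cannot be decrypted (wrong key or tampering)."""
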