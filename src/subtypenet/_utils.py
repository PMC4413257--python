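"""Shared helpers: seed derivation, validation, logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("subtypenet")

LUMINAL = "luminal-A"
BASAL = "basal-like"
SUBTYPES = (LUMINAL, BASAL)

GROUPS = ("luminalA_gain", "luminalA_loss", "basal_gain", "basal_loss")


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


class DataConsistencyError(ValueError):
    """Inputs disagree with each other (samples, genes, chromosomes...)."""


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific RNG seed from a single top-level seed.

    Stable across runs and platforms (blake2 of ``"{seed}:{stage}"``),
    always below 2**31 so it can be fed to any RNG.
    """
    h = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31)


def require(cond: bool, exc: type[Exception], msg: str) -> None:
    if not cond:
        raise exc(msg)
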