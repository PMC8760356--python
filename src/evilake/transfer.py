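"""Registration orchestration: the transfer pattern.

A registration mints a PID, validates and persists the metadata record,
stores and digest-verifies the payload, and links the stored location back
into the metadata — atomically.  On any failure (digest mismatch, dangling
provenance reference, cycle) neither the record nor the object persists.

Metadata-only registration (``payload=None``) is supported so software or
data hosted in an external archive can still be cited: the record resolves
with ``content_location=None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from random import Random
from typing import BinaryIO, Optional, Union

from .errors import IntegrityError, ValidationError
from .identifiers import PID
from .model import Draft, validate_record
from .registry import Registry
from .store import ObjectStore, StoredObject


@dataclass(frozen=True)
class RegistrationReceipt:
    """Returned by a successful registration."""

    pid: PID
    stored: Optional[StoredObject]
    evidence_graph_link: str


def register(
    registry: Registry,
    store: ObjectStore,
    rng: Random,
    naan: str,
    shoulder: str,
    draft: Draft,
    payload: Optional[Union[bytes, BinaryIO]] = None,
    claimed_sha256: Optional[str] = None,
    filename: Optional[str] = None,
) -> RegistrationReceipt:
    """Register one object (payload plus metadata, or metadata only).

    The payload's claimed SHA-256 is recomputed during the write; a mismatch
    aborts the whole registration.  ``filename`` only affects the on-disk
    location (``{ark-name}/{filename}``), which matters to executors that
    stage inputs by basename.
    """
    if payload is not None and claimed_sha256 is None:
        raise ValidationError("a payload requires a claimed sha256 digest")
    if payload is None and claimed_sha256 is not None:
        raise ValidationError("a claimed sha256 digest requires a payload")

    pid = registry.mint(naan, shoulder, rng)
    record = draft.to_record(pid, created_at=registry.timestamp())
    # Fail fast on metadata problems before any bytes are written.
    violations = validate_record(record, registry.get)
    if violations:
        raise ValidationError(violations)

    stored: Optional[StoredObject] = None
    if payload is not None:
        location = f"{pid.name}/{filename or 'object'}"
        stored = store.store(payload, claimed_sha256, location)
        record = record.evolve(
            checksum=stored.sha256, content_location=stored.location
        )
    try:
        registry.create(record)
    except Exception:
        if stored is not None:
            store.remove(stored.location)
        raise
    return RegistrationReceipt(
        pid=pid,
        stored=stored,
        evidence_graph_link=registry.evidence_graph_link(pid),
    )
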