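"""Object deletion with metadata permanence.

Deleting an object removes its bytes from the store but retains its full
metadata record — provenance edges, name, version, checksum — so the PID
stays citable and every evidence graph it appears in is unchanged.  The
tombstone keeps the prior location and digest so a later re-deposit can be
verified as the same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NotFoundError, StateError
from .identifiers import PID, as_pid


@dataclass(frozen=True)
class Tombstone:
    """Marker left behind when an object's bytes are removed."""

    pid: PID
    deleted_at: str
    prior_location: str
    prior_sha256: str


def delete_object(registry, store, pid) -> Tombstone:
    """Remove the stored bytes for *pid*, keeping its metadata resolvable.

    Raises :class:`NotFoundError` for unknown PIDs and :class:`StateError`
    when the record is metadata-only or already tombstoned.
    """
    pid = as_pid(pid)
    record = registry.resolve(pid)
    if getattr(record, "content_location", None) is None:
        if registry.tombstone_for(pid) is not None:
            raise StateError(f"{pid} is already tombstoned")
        raise StateError(f"{pid} has no stored object to delete")
    location = record.content_location
    tomb = registry.apply_tombstone(pid, deleted_at=registry.timestamp())
    try:
        store.remove(location)
    except NotFoundError:
        # Bytes already gone out-of-band; the tombstone still records intent.
        pass
    return tomb
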