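"""Content storage with cryptographic integrity.

Objects live under a root directory as plain files addressed by POSIX-style
relative locations.  Every write streams the payload through SHA-256 in
fixed-size chunks and compares the result against the digest the caller
claims; a mismatch removes the partial write and persists nothing.  Every
read recomputes the digest and compares it with the one recorded in the
store's manifest, so silent corruption is detected at access time.

Writes go to a temporary file first and are renamed into place, so a
partially written object is never observable.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
import shutil
from dataclasses import dataclass
from pathlib import Path, PurePosixPath
from typing import BinaryIO, Optional, Union

from .errors import ConflictError, CorruptionError, IntegrityError, NotFoundError

CHUNK_SIZE = 1 << 20  # 1 MiB; memory use is independent of object size

_MANIFEST_NAME = "_manifest.jsonl"


@dataclass(frozen=True)
class StoredObject:
    """Receipt for one stored payload."""

    location: str
    sha256: str
    size: int


def sha256_hex(payload: Union[bytes, BinaryIO]) -> str:
    """Streaming SHA-256 of bytes or a binary file object."""
    h = hashlib.sha256()
    if isinstance(payload, (bytes, bytearray)):
        h.update(payload)
    else:
        for chunk in iter(lambda: payload.read(CHUNK_SIZE), b""):
            h.update(chunk)
    return h.hexdigest()


def _safe_relative(location: str) -> PurePosixPath:
    rel = PurePosixPath(location)
    if rel.is_absolute() or any(part in ("..", "") for part in rel.parts):
        raise ValueError(f"unsafe store location: {location!r}")
    if not rel.parts:
        raise ValueError("empty store location")
    if rel.parts[0].startswith("_"):
        raise ValueError(f"locations under '_' are reserved: {location!r}")
    return rel


class ObjectStore:
    """Filesystem-backed object store with digest verification."""

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.root / _MANIFEST_NAME
        self._manifest: dict[str, StoredObject] = {}
        if self._manifest_path.exists():
            self._load_manifest()

    # ------------------------------------------------------------------ write

    def store(
        self,
        payload: Union[bytes, BinaryIO],
        claimed_sha256: str,
        location: str,
        version: bool = False,
    ) -> StoredObject:
        """Persist *payload* at *location*, verifying the claimed digest.

        With ``version=True`` an occupied location gets a ``.vN`` suffix
        instead of raising :class:`ConflictError`; the existing bytes are
        untouched.
        """
        rel = _safe_relative(location)
        if str(rel) in self._manifest:
            if not version:
                raise ConflictError(f"location occupied: {location}")
            n = 2
            while f"{rel}.v{n}" in self._manifest:
                n += 1
            rel = PurePosixPath(f"{rel}.v{n}")
        target = self.root / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        tmp = target.with_name(target.name + ".part")

        h = hashlib.sha256()
        size = 0
        stream: BinaryIO = (
            io.BytesIO(payload) if isinstance(payload, (bytes, bytearray)) else payload
        )
        try:
            with tmp.open("wb") as out:
                for chunk in iter(lambda: stream.read(CHUNK_SIZE), b""):
                    h.update(chunk)
                    size += len(chunk)
                    out.write(chunk)
            digest = h.hexdigest()
            if digest != claimed_sha256:
                raise IntegrityError(
                    f"digest mismatch at {rel}: claimed {claimed_sha256}, "
                    f"computed {digest}; nothing stored"
                )
            os.replace(tmp, target)
        finally:
            if tmp.exists():
                tmp.unlink()
            # drop any directories created for a write that never happened
            parent = target.parent
            while parent != self.root and not any(parent.iterdir()):
                parent.rmdir()
                parent = parent.parent
        obj = StoredObject(location=str(rel), sha256=digest, size=size)
        self._manifest[obj.location] = obj
        self._append_manifest({"op": "put", **obj.__dict__})
        return obj

    # ------------------------------------------------------------------- read

    def retrieve(self, location: str) -> bytes:
        """Return the stored bytes, re-verifying the digest first."""
        obj = self._lookup(location)
        path = self.root / obj.location
        if not path.exists():
            raise NotFoundError(f"object bytes missing at {location}")
        data = path.read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != obj.sha256:
            raise CorruptionError(
                f"stored bytes at {location} hash to {digest}, "
                f"expected {obj.sha256}"
            )
        return data

    def retrieve_to(self, location: str, destination: Union[str, Path]) -> Path:
        """Copy a verified object to *destination* (used by compute staging)."""
        obj = self._lookup(location)
        src = self.root / obj.location
        if not src.exists():
            raise NotFoundError(f"object bytes missing at {location}")
        dest = Path(destination)
        dest.parent.mkdir(parents=True, exist_ok=True)
        h = hashlib.sha256()
        with src.open("rb") as fin, dest.open("wb") as fout:
            for chunk in iter(lambda: fin.read(CHUNK_SIZE), b""):
                h.update(chunk)
                fout.write(chunk)
        if h.hexdigest() != obj.sha256:
            dest.unlink(missing_ok=True)
            raise CorruptionError(
                f"stored bytes at {location} hash to {h.hexdigest()}, "
                f"expected {obj.sha256}"
            )
        return dest

    def exists(self, location: str) -> bool:
        return location in self._manifest

    def describe(self, location: str) -> StoredObject:
        return self._lookup(location)

    # ----------------------------------------------------------------- delete

    def remove(self, location: str) -> StoredObject:
        """Delete the bytes at *location*; siblings are unaffected."""
        obj = self._lookup(location)
        path = self.root / obj.location
        if path.exists():
            path.unlink()
        del self._manifest[obj.location]
        self._append_manifest({"op": "delete", "location": obj.location})
        return obj

    # ------------------------------------------------------------- internals

    def _lookup(self, location: str) -> StoredObject:
        obj = self._manifest.get(str(_safe_relative(location)))
        if obj is None:
            raise NotFoundError(f"no object at location {location}")
        return obj

    def _append_manifest(self, event: dict) -> None:
        with self._manifest_path.open("a", encoding="utf-8") as fh:
            fh.write(json.dumps(event, sort_keys=True, separators=(",", ":")) + "\n")

    def _load_manifest(self) -> None:
        with self._manifest_path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                event = json.loads(line)
                if event["op"] == "put":
                    obj = StoredObject(
                        location=event["location"],
                        sha256=event["sha256"],
                        size=event["size"],
                    )
                    self._manifest[obj.location] = obj
                elif event["op"] == "delete":
                    self._manifest.pop(event["location"], None)

    def snapshot(self) -> dict[str, StoredObject]:
        """Current manifest (location → object), for atomicity checks."""
        return dict(self._manifest)
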