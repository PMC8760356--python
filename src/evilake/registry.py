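"""Durable keyed store of metadata records with a provenance edge index.

The registry is the in-process metadata service: a single-writer,
multi-reader document store persisted as an append-only JSON-lines log,
with an in-memory :class:`networkx.DiGraph` indexing the provenance edges
implied by the records.  Two invariants are enforced on every write:

* the edge index is exactly the edges implied by the stored records, and
* the edge relation is acyclic (evidence graphs are support DAGs).

Timestamps are a deterministic logical clock (a fixed epoch plus one second
per registry event), so registries built from equal seeds serialize
bit-identically.
"""

from __future__ import annotations

import json
from datetime import datetime, timedelta, timezone
from pathlib import Path
from random import Random
from typing import Any, Iterator, Optional, Union

import networkx as nx

from .deletion import Tombstone
from .errors import (
    ConflictError,
    CycleError,
    NotFoundError,
    StateError,
    ValidationError,
)
from .identifiers import PID, as_pid, mint_pid
from .model import (
    ChallengeRecord,
    EviType,
    MetadataRecord,
    challenge_from_jsonld,
    challenge_to_jsonld,
    from_jsonld,
    to_jsonld,
    validate_record,
)

#: Provenance predicates that form support edges.
SUPPORT_PREDICATES = ("generatedBy", "usedDataset", "usedSoftware")

Edge = tuple[PID, str, PID]

_EPOCH = datetime(2021, 1, 1, tzinfo=timezone.utc)

#: Patchable record fields for :meth:`Registry.update`.
_PATCHABLE = frozenset(
    {
        "name",
        "description",
        "author",
        "checksum",
        "content_location",
        "used_datasets",
        "used_software",
        "generated_by",
        "parameters",
        "extras",
    }
)


def implied_edges(record: MetadataRecord) -> list[Edge]:
    """The support edges a single record contributes to the index."""
    edges: list[Edge] = []
    if record.generated_by is not None:
        edges.append((record.pid, "generatedBy", record.generated_by))
    for d in record.used_datasets:
        edges.append((record.pid, "usedDataset", d))
    for s in record.used_software:
        edges.append((record.pid, "usedSoftware", s))
    return edges


class Registry:
    """Metadata store with create/resolve/update/tombstone semantics.

    Parameters
    ----------
    path:
        Location of the JSON-lines event log.  ``None`` keeps the registry
        purely in memory (events are still accumulated for
        :meth:`snapshot_bytes`).
    """

    def __init__(self, path: Optional[Union[str, Path]] = None):
        self.path = Path(path) if path is not None else None
        self._records: dict[PID, MetadataRecord] = {}
        self._aliases: dict[PID, PID] = {}
        self._challenges: dict[PID, ChallengeRecord] = {}
        self._tombstones: dict[PID, Tombstone] = {}
        self._history: dict[PID, list[MetadataRecord]] = {}
        self._graph = nx.MultiDiGraph()
        self._events: list[str] = []
        self._clock = 0
        if self.path is not None and self.path.exists():
            self._replay(self.path)

    # ------------------------------------------------------------------ clock

    def timestamp(self) -> str:
        """Next tick of the deterministic logical clock, as ISO-8601."""
        self._clock += 1
        return (_EPOCH + timedelta(seconds=self._clock)).isoformat()

    # ------------------------------------------------------------ identifiers

    def mint(self, naan: str, shoulder: str, rng: Random) -> PID:
        """Mint a PID guaranteed unused within this registry."""
        while True:
            pid = mint_pid(naan, shoulder, rng)
            if not self._known(pid):
                return pid

    def _known(self, pid: PID) -> bool:
        return (
            pid in self._records
            or pid in self._aliases
            or pid in self._challenges
        )

    # ------------------------------------------------------------------ reads

    def canonical(self, pid: Union[PID, str]) -> PID:
        """Follow alias indirection to the canonical PID."""
        pid = as_pid(pid)
        seen = set()
        while pid in self._aliases:
            if pid in seen:  # defensive; alias cycles are rejected on write
                raise StateError(f"alias cycle at {pid}")
            seen.add(pid)
            pid = self._aliases[pid]
        return pid

    def get(
        self, pid: Union[PID, str]
    ) -> Optional[Union[MetadataRecord, ChallengeRecord]]:
        """Resolver-style lookup: record, challenge, or ``None``."""
        try:
            pid = self.canonical(pid)
        except Exception:
            return None
        return self._records.get(pid) or self._challenges.get(pid)

    def resolve(
        self, pid: Union[PID, str]
    ) -> Union[MetadataRecord, ChallengeRecord]:
        """Return the record for *pid*, following aliases.

        Tombstoned records still resolve (with ``content_location=None``);
        unknown PIDs raise :class:`NotFoundError`.
        """
        found = self.get(pid)
        if found is None:
            raise NotFoundError(f"unknown PID: {as_pid(pid)}")
        return found

    def resolve_document(self, pid: Union[PID, str]) -> dict[str, Any]:
        """Resolve to a JSON-LD document, including the evidence-graph link."""
        found = self.resolve(pid)
        if isinstance(found, ChallengeRecord):
            doc = challenge_to_jsonld(found)
        else:
            doc = to_jsonld(found)
        doc["evidenceGraph"] = self.evidence_graph_link(found.pid)
        return doc

    @staticmethod
    def evidence_graph_link(pid: Union[PID, str]) -> str:
        return f"/evidence-graph/{as_pid(pid)}"

    def __contains__(self, pid: object) -> bool:
        try:
            return self.get(pid) is not None  # type: ignore[arg-type]
        except Exception:
            return False

    def iter_records(self) -> Iterator[MetadataRecord]:
        """Records in insertion order."""
        return iter(list(self._records.values()))

    def iter_challenges(self) -> Iterator[ChallengeRecord]:
        return iter(list(self._challenges.values()))

    def history(self, pid: Union[PID, str]) -> list[MetadataRecord]:
        """Prior versions of a record, oldest first (audit trail)."""
        return list(self._history.get(self.canonical(pid), []))

    def tombstone_for(self, pid: Union[PID, str]) -> Optional[Tombstone]:
        return self._tombstones.get(self.canonical(pid))

    @property
    def edges(self) -> list[Edge]:
        """All support edges, canonicalized, in deterministic order."""
        out = [(u, p, v) for u, v, p in self._graph.edges(keys=True)]
        return sorted(out, key=lambda e: (str(e[0]), e[1], str(e[2])))

    def graph_view(self) -> nx.MultiDiGraph:
        """A read-only-by-convention view of the edge index."""
        return self._graph

    # ----------------------------------------------------------------- writes

    def create(self, record: MetadataRecord) -> PID:
        """Persist a new record and index its edges atomically."""
        if self._known(record.pid):
            raise ConflictError(f"PID already registered: {record.pid}")
        violations = validate_record(record, self.get)
        if violations:
            raise ValidationError(violations)
        edges = [(u, p, self.canonical(v)) for u, p, v in implied_edges(record)]
        # A fresh PID has no incoming edges, so its out-edges cannot close a
        # cycle; guard anyway so the invariant never depends on that argument.
        for _, _, target in edges:
            if target == record.pid:
                raise CycleError([record.pid, record.pid])
        self._records[record.pid] = record
        self._graph.add_node(record.pid)
        self._add_edges(edges)
        self._persist({"op": "create", "record": self._doc(record)})
        return record.pid

    def update(
        self, pid: Union[PID, str], patch: dict[str, Any]
    ) -> MetadataRecord:
        """Apply a partial patch: version bumps, edges re-indexed atomically.

        On any rejection (validation, dangling reference, cycle) the registry
        state is unchanged and the prior version still resolves.
        """
        pid = self.canonical(pid)
        old = self._records.get(pid)
        if old is None:
            raise NotFoundError(f"unknown PID: {pid}")
        bad_keys = set(patch) - _PATCHABLE
        if bad_keys:
            raise ValidationError(
                [f"field not patchable: {k}" for k in sorted(bad_keys)]
            )
        changes = dict(patch)
        for key in ("used_datasets", "used_software"):
            if key in changes:
                changes[key] = tuple(as_pid(p) for p in changes[key])
        for key in ("generated_by", "parameters"):
            if key in changes and changes[key] is not None:
                changes[key] = as_pid(changes[key])
        new = old.evolve(**changes, version=old.version + 1)
        violations = validate_record(new, self.get)
        if violations:
            raise ValidationError(violations)

        old_edges = [(u, p, self.canonical(v)) for u, p, v in implied_edges(old)]
        new_edges = [(u, p, self.canonical(v)) for u, p, v in implied_edges(new)]
        if set(old_edges) != set(new_edges):
            trial = self._graph.copy()
            for u, p, v in old_edges:
                if trial.has_edge(u, v, key=p):
                    trial.remove_edge(u, v, key=p)
            for u, p, v in new_edges:
                trial.add_edge(u, v, key=p)
            try:
                cycle = nx.find_cycle(trial, orientation="original")
            except nx.NetworkXNoCycle:
                cycle = None
            if cycle:
                path = [edge[0] for edge in cycle] + [cycle[0][0]]
                raise CycleError(path)
            self._graph = trial
        self._history.setdefault(pid, []).append(old)
        self._records[pid] = new
        self._persist({"op": "update", "record": self._doc(new)})
        return new

    def add_alias(self, alias: PID, canonical: Union[PID, str]) -> None:
        """Register *alias* as an alternative PID for an existing record.

        Aliases resolve to the canonical record but never appear as graph
        nodes.
        """
        canonical = self.canonical(canonical)
        if canonical not in self._records and canonical not in self._challenges:
            raise NotFoundError(f"unknown PID: {canonical}")
        if self._known(alias):
            raise ConflictError(f"PID already registered: {alias}")
        self._aliases[alias] = canonical
        self._persist(
            {"op": "alias", "alias": str(alias), "canonical": str(canonical)}
        )

    def register_challenge(self, challenge: ChallengeRecord) -> PID:
        """Persist a challenge; support edges are never modified."""
        if self._known(challenge.pid):
            raise ConflictError(f"PID already registered: {challenge.pid}")
        if self.get(challenge.target) is None:
            raise NotFoundError(f"unknown PID: {challenge.target}")
        self._challenges[challenge.pid] = challenge
        self._persist(
            {"op": "challenge", "record": self._doc_challenge(challenge)}
        )
        return challenge.pid

    def apply_tombstone(self, pid: Union[PID, str], deleted_at: str) -> Tombstone:
        """Null out a record's content location, retaining all other fields.

        The prior location and digest are kept on the tombstone so a later
        re-deposit can be verified against the original bytes.
        """
        pid = self.canonical(pid)
        record = self._records.get(pid)
        if record is None:
            raise NotFoundError(f"unknown PID: {pid}")
        if record.content_location is None:
            raise StateError(f"{pid} has no stored object to delete")
        tomb = Tombstone(
            pid=pid,
            deleted_at=deleted_at,
            prior_location=record.content_location,
            prior_sha256=record.checksum or "",
        )
        # Location nulled in place: provenance, version, and every other
        # field stay intact so the record remains citable.
        self._records[pid] = record.evolve(content_location=None)
        self._tombstones[pid] = tomb
        self._persist(
            {
                "op": "tombstone",
                "pid": str(pid),
                "deleted_at": tomb.deleted_at,
                "prior_location": tomb.prior_location,
                "prior_sha256": tomb.prior_sha256,
            }
        )
        return tomb

    # ----------------------------------------------------------- index upkeep

    def _add_edges(self, edges: list[Edge]) -> None:
        for u, p, v in edges:
            self._graph.add_edge(u, v, key=p)

    def rebuild_edge_index(self) -> nx.MultiDiGraph:
        """Recompute the edge index from the records alone (oracle check)."""
        g = nx.MultiDiGraph()
        for record in self._records.values():
            g.add_node(record.pid)
            for u, p, v in implied_edges(record):
                g.add_edge(u, self.canonical(v), key=p)
        return g

    # ------------------------------------------------------------ persistence

    def _doc(self, record: MetadataRecord) -> dict[str, Any]:
        doc = to_jsonld(record)
        doc.pop("@context", None)  # the context is static; keep the log lean
        return doc

    def _doc_challenge(self, challenge: ChallengeRecord) -> dict[str, Any]:
        doc = challenge_to_jsonld(challenge)
        doc.pop("@context", None)
        return doc

    def _persist(self, event: dict[str, Any]) -> None:
        line = json.dumps(event, sort_keys=True, separators=(",", ":"))
        self._events.append(line)
        if self.path is not None:
            with self.path.open("a", encoding="utf-8") as fh:
                fh.write(line + "\n")

    def snapshot_bytes(self) -> bytes:
        """The full serialized event log (what the on-disk file contains)."""
        if not self._events:
            return b""
        return ("\n".join(self._events) + "\n").encode("utf-8")

    def _replay(self, path: Path) -> None:
        """Rebuild in-memory state from an existing event log."""
        with path.open(encoding="utf-8") as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        for line in lines:
            event = json.loads(line)
            op = event["op"]
            if op == "create":
                record = from_jsonld(event["record"])
                self._records[record.pid] = record
                self._graph.add_node(record.pid)
                self._add_edges(
                    [
                        (u, p, self.canonical(v))
                        for u, p, v in implied_edges(record)
                    ]
                )
            elif op == "update":
                record = from_jsonld(event["record"])
                old = self._records[record.pid]
                self._history.setdefault(record.pid, []).append(old)
                for u, p, v in implied_edges(old):
                    v = self.canonical(v)
                    if self._graph.has_edge(u, v, key=p):
                        self._graph.remove_edge(u, v, key=p)
                self._records[record.pid] = record
                self._add_edges(
                    [
                        (u, p, self.canonical(v))
                        for u, p, v in implied_edges(record)
                    ]
                )
            elif op == "alias":
                self._aliases[as_pid(event["alias"])] = as_pid(event["canonical"])
            elif op == "challenge":
                ch = challenge_from_jsonld(event["record"])
                self._challenges[ch.pid] = ch
            elif op == "tombstone":
                pid = as_pid(event["pid"])
                tomb = Tombstone(
                    pid=pid,
                    deleted_at=event["deleted_at"],
                    prior_location=event["prior_location"],
                    prior_sha256=event["prior_sha256"],
                )
                self._records[pid] = self._records[pid].evolve(
                    content_location=None
                )
                self._tombstones[pid] = tomb
            else:  # pragma: no cover - defensive
                raise ValueError(f"unknown registry event op {op!r}")
        self._events = lines
        self._clock = len(lines)
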