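"""The `Commons` facade: one provenance-aware data commons rooted at a directory.

A :class:`Commons` wires together the identifier mint, metadata registry,
object store, transfer orchestration, compute service, evidence-graph
extraction, search, and deletion behind a single object::

    commons = Commons(root, naan="59852", seed=1)
    receipt = commons.register(Draft(EviType.DATASET, "Raw vitals"),
                               payload=b"...", sha256=digest)
    job = commons.submit([receipt.pid], script_pid, engine="noop",
                         executor=my_step)
    commons.run_job(job)
    graph = commons.evidence_graph(job.output_pids[0])

All randomness (PID blades) flows from the single seed, and timestamps come
from the registry's logical clock, so two commons built by the same
operations with the same seed serialize bit-identically.
"""

from __future__ import annotations

from pathlib import Path
from random import Random
from typing import BinaryIO, Optional, Sequence, Union

from . import graph as graph_mod
from .compute import ComputeService, ExecutorFn, Job
from .deletion import Tombstone, delete_object
from .identifiers import PID, as_pid
from .model import ChallengeRecord, Draft, MetadataRecord
from .registry import Registry
from .search import SearchResult, search_literals
from .store import ObjectStore
from .transfer import RegistrationReceipt, register

DEFAULT_NAAN = "59852"
DEFAULT_SHOULDER = "fk4"


class Commons:
    """A self-contained data commons on the local filesystem."""

    def __init__(
        self,
        root: Union[str, Path],
        naan: str = DEFAULT_NAAN,
        shoulder: str = DEFAULT_SHOULDER,
        seed: int = 0,
    ):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.naan = naan
        self.shoulder = shoulder
        self.rng = Random(seed)
        self.registry = Registry(self.root / "registry.jsonl")
        self.store = ObjectStore(self.root / "objects")
        self.compute = ComputeService(
            self.registry,
            self.store,
            self.rng,
            naan,
            shoulder,
            scratch_root=self.root / "scratch",
        )

    # ------------------------------------------------------------ registration

    def register(
        self,
        draft: Draft,
        payload: Optional[Union[bytes, BinaryIO]] = None,
        sha256: Optional[str] = None,
        filename: Optional[str] = None,
    ) -> RegistrationReceipt:
        """Register an object (or metadata-only record); atomic on failure."""
        return register(
            self.registry,
            self.store,
            self.rng,
            self.naan,
            self.shoulder,
            draft,
            payload=payload,
            claimed_sha256=sha256,
            filename=filename,
        )

    def resolve(self, pid: Union[PID, str]):
        return self.registry.resolve(pid)

    def resolve_document(self, pid: Union[PID, str]) -> dict:
        return self.registry.resolve_document(pid)

    def update(self, pid: Union[PID, str], patch: dict) -> MetadataRecord:
        return self.registry.update(pid, patch)

    def add_alias(self, canonical: Union[PID, str]) -> PID:
        """Mint an alternative PID resolving to an existing record."""
        alias = self.registry.mint(self.naan, self.shoulder, self.rng)
        self.registry.add_alias(alias, as_pid(canonical))
        return alias

    def retrieve(self, pid: Union[PID, str]) -> bytes:
        """Fetch a registered object's verified bytes by PID."""
        record = self.registry.resolve(pid)
        if record.content_location is None:
            from .errors import NotFoundError

            raise NotFoundError(f"{as_pid(pid)} holds no stored object")
        return self.store.retrieve(record.content_location)

    # ----------------------------------------------------------------- compute

    def submit(
        self,
        dataset_pids: Sequence[Union[PID, str]],
        software_pid: Union[PID, str],
        engine: str = "local",
        parameters: Optional[dict] = None,
        *,
        executor: Optional[ExecutorFn] = None,
        name: str = "",
        description: str = "",
        author: str = "",
        output_metadata: Optional[dict] = None,
    ) -> Job:
        return self.compute.submit(
            dataset_pids,
            software_pid,
            engine=engine,
            parameters=parameters,
            executor=executor,
            name=name,
            description=description,
            author=author,
            output_metadata=output_metadata,
        )

    def run_job(self, job: Union[Job, str]) -> Job:
        return self.compute.run_to_completion(job)

    def job_status(self, job_id: str) -> Job:
        return self.compute.job_status(job_id)

    # ----------------------------------------------------------- evidence graph

    def evidence_graph(
        self, pid: Union[PID, str], include_parameters: bool = False
    ) -> graph_mod.EvidenceGraph:
        return graph_mod.extract(
            self.registry, pid, include_parameters=include_parameters
        )

    def challenge(
        self, target: Union[PID, str], category: str, description: str = ""
    ) -> ChallengeRecord:
        return graph_mod.challenge(
            self.registry,
            self.rng,
            self.naan,
            self.shoulder,
            target,
            category,
            description,
        )

    def undermined(
        self, pid: Union[PID, str], include_parameters: bool = False
    ) -> list[graph_mod.UnderminedFinding]:
        return graph_mod.undermined(
            self.registry, pid, include_parameters=include_parameters
        )

    # ------------------------------------------------------------------- search

    def search(self, query: str) -> SearchResult:
        return search_literals(self.registry, query)

    # ----------------------------------------------------------------- deletion

    def delete_object(self, pid: Union[PID, str]) -> Tombstone:
        return delete_object(self.registry, self.store, pid)
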