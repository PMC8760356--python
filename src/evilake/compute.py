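"""Provenance-capturing computation.

Submitting a job mints a Computation record *before* anything runs, linked
to its inputs by ``usedDataset`` and to its script by ``usedSoftware``.
Runtime parameters, when given, are minted as their own record and linked
via the ``parameters`` property (they stay out of evidence graphs unless
explicitly requested at extraction time).  On completion, every file the
executor left in the output area is registered through the transfer path
with ``generatedBy`` pointing at the computation, typed Image for raster
extensions and Dataset otherwise.  On failure nothing is registered and the
computation record is annotated, so failures remain auditable.

Executors never see raw PIDs: inputs are dereferenced from the object store
and staged under a ``data/`` directory; outputs are collected from an
``outputs/`` directory.  Two engines are available — ``local`` runs the
registered software payload as a Python script in a scratch directory, and
``noop`` runs a caller-supplied in-process callable (used by fixtures and
provenance-only runs).  The ``spark`` and ``nipype`` engine names are
recognized but not available in this build and raise a configuration error.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import sys
import traceback
from dataclasses import dataclass, field, replace
from pathlib import Path
from random import Random
from typing import Callable, Optional, Sequence, Union

from .errors import ConfigurationError, NotFoundError, StateError, ValidationError
from .identifiers import PID, as_pid
from .model import Draft, EviType, MetadataRecord
from .registry import Registry
from .store import ObjectStore, sha256_hex
from .transfer import register

#: File extensions registered as Image outputs; everything else is Dataset.
IMAGE_EXTENSIONS = frozenset(
    {".png", ".jpg", ".jpeg", ".gif", ".bmp", ".tif", ".tiff", ".svg"}
)

ENGINES = ("local", "noop", "spark", "nipype")

#: An executor receives the staged input directory and the output directory.
ExecutorFn = Callable[[Path, Path], None]


@dataclass
class Job:
    """State record of one submitted computation."""

    job_id: str
    computation_pid: PID
    state: str = "queued"  # queued -> running -> completed | failed
    output_pids: list[PID] = field(default_factory=list)
    log: str = ""


def infer_output_type(filename: str) -> EviType:
    suffix = Path(filename).suffix.lower()
    return EviType.IMAGE if suffix in IMAGE_EXTENSIONS else EviType.DATASET


class ComputeService:
    """Local stand-in for a cluster compute service, same provenance contract."""

    def __init__(
        self,
        registry: Registry,
        store: ObjectStore,
        rng: Random,
        naan: str,
        shoulder: str,
        scratch_root: Union[str, Path],
    ):
        self.registry = registry
        self.store = store
        self.rng = rng
        self.naan = naan
        self.shoulder = shoulder
        self.scratch_root = Path(scratch_root)
        self._jobs: dict[str, Job] = {}
        self._executors: dict[str, ExecutorFn] = {}
        self._output_metadata: dict[str, dict[str, dict]] = {}
        self._counter = 0

    # ----------------------------------------------------------------- submit

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
        output_metadata: Optional[dict[str, dict]] = None,
    ) -> Job:
        """Mint a Computation record and queue a job.

        All referenced PIDs must resolve before anything is minted.  With
        ``engine="noop"`` the caller supplies *executor*, an in-process
        callable ``(data_dir, out_dir) -> None``.  *output_metadata* maps an
        output filename to draft fields (``name``, ``description``, ...)
        for the auto-registered outputs.
        """
        if engine not in ENGINES:
            raise ConfigurationError(
                f"unknown engine {engine!r}; expected one of {ENGINES}"
            )
        if engine in ("spark", "nipype"):
            raise ConfigurationError(
                f"engine {engine!r} is not available in this build; "
                "use 'local' or 'noop'"
            )
        if engine == "noop" and executor is None:
            raise ConfigurationError("engine 'noop' requires an executor callable")
        if engine == "local" and executor is not None:
            raise ConfigurationError("engine 'local' does not take an executor")

        datasets = [as_pid(p) for p in dataset_pids]
        software = as_pid(software_pid)
        for pid in [*datasets, software]:
            self.registry.resolve(pid)  # NotFoundError before anything mints
        software_record = self.registry.resolve(software)
        if engine == "local" and software_record.content_location is None:
            raise StateError(
                f"software {software} has no retrievable payload; "
                "the 'local' engine needs one"
            )

        parameters_pid: Optional[PID] = None
        if parameters is not None:
            parameters_pid = self._mint_parameters(parameters)

        comp_pid = self.registry.mint(self.naan, self.shoulder, self.rng)
        comp = MetadataRecord(
            pid=comp_pid,
            evi_type=EviType.COMPUTATION,
            name=name or f"Computation {comp_pid.name}",
            description=description,
            author=author,
            used_datasets=tuple(datasets),
            used_software=(software,),
            parameters=parameters_pid,
            created_at=self.registry.timestamp(),
            extras=(("engine", engine), ("status", "queued")),
        )
        self.registry.create(comp)

        self._counter += 1
        job = Job(job_id=f"job-{self._counter:06d}", computation_pid=comp_pid)
        self._jobs[job.job_id] = job
        if executor is not None:
            self._executors[job.job_id] = executor
        self._output_metadata[job.job_id] = output_metadata or {}
        return job

    def _mint_parameters(self, parameters: dict) -> PID:
        pid = self.registry.mint(self.naan, self.shoulder, self.rng)
        record = MetadataRecord(
            pid=pid,
            evi_type=EviType.DATASET,
            name="Runtime parameters",
            description=json.dumps(parameters, sort_keys=True),
            created_at=self.registry.timestamp(),
            extras=(("parameterValues", dict(sorted(parameters.items()))),),
        )
        self.registry.create(record)
        return pid

    # -------------------------------------------------------------------- run

    def run_to_completion(self, job: Union[Job, str]) -> Job:
        """Execute a queued job synchronously and register its outputs."""
        job = self._jobs[job] if isinstance(job, str) else job
        if job.state != "queued":
            raise StateError(f"job {job.job_id} is {job.state}, not queued")
        job.state = "running"

        scratch = self.scratch_root / job.job_id
        data_dir = scratch / "data"
        out_dir = scratch / "outputs"
        try:
            data_dir.mkdir(parents=True, exist_ok=True)
            out_dir.mkdir(parents=True, exist_ok=True)
            comp = self.registry.resolve(job.computation_pid)
            self._stage_inputs(comp, data_dir)
            executor = self._executors.get(job.job_id)
            if executor is not None:
                executor(data_dir, out_dir)
            else:
                self._run_local(comp, scratch, data_dir, out_dir, job)
        except Exception as exc:
            job.state = "failed"
            job.log += f"executor failed: {exc}\n{traceback.format_exc()}"
            self._annotate(job.computation_pid, "failed")
            self._executors.pop(job.job_id, None)
            shutil.rmtree(scratch, ignore_errors=True)
            return job
        self._executors.pop(job.job_id, None)

        try:
            output_meta = self._output_metadata.get(job.job_id, {})
            outputs = sorted(
                (p for p in out_dir.rglob("*") if p.is_file()),
                key=lambda p: str(p.relative_to(out_dir)),
            )
            pids: list[PID] = []
            for path in outputs:
                rel = str(path.relative_to(out_dir))
                meta = output_meta.get(rel, {})
                payload = path.read_bytes()
                draft = Draft(
                    evi_type=infer_output_type(rel),
                    name=meta.get("name", rel),
                    description=meta.get("description", ""),
                    author=meta.get("author", ""),
                    generated_by=job.computation_pid,
                )
                receipt = register(
                    self.registry,
                    self.store,
                    self.rng,
                    self.naan,
                    self.shoulder,
                    draft,
                    payload=payload,
                    claimed_sha256=sha256_hex(payload),
                    filename=Path(rel).name,
                )
                pids.append(receipt.pid)
            job.output_pids = pids
            job.state = "completed"
            self._annotate(job.computation_pid, "completed")
        except Exception as exc:
            job.state = "failed"
            job.log += f"output registration failed: {exc}\n"
            self._annotate(job.computation_pid, "failed")
        finally:
            shutil.rmtree(scratch, ignore_errors=True)
        return job

    def _stage_inputs(self, comp: MetadataRecord, data_dir: Path) -> None:
        for pid in comp.used_datasets:
            record = self.registry.resolve(pid)
            if record.content_location is None:
                continue  # metadata-only input; nothing to stage
            basename = Path(record.content_location).name
            dest = data_dir / basename
            if dest.exists():  # two inputs sharing a basename
                dest = data_dir / f"{pid.name}-{basename}"
            self.store.retrieve_to(record.content_location, dest)

    def _run_local(
        self,
        comp: MetadataRecord,
        scratch: Path,
        data_dir: Path,
        out_dir: Path,
        job: Job,
    ) -> None:
        software = self.registry.resolve(comp.used_software[0])
        script = scratch / Path(software.content_location).name
        self.store.retrieve_to(software.content_location, script)
        # The local engine's contract: the payload is a Python script invoked
        # with the staged input directory and the output directory as argv.
        proc = subprocess.run(
            [sys.executable, str(script), str(data_dir), str(out_dir)],
            capture_output=True,
            text=True,
            timeout=600,
        )
        job.log += proc.stdout + proc.stderr
        if proc.returncode != 0:
            raise RuntimeError(
                f"local executor exited with status {proc.returncode}"
            )

    def _annotate(self, comp_pid: PID, status: str) -> None:
        comp = self.registry.resolve(comp_pid)
        extras = comp.extras_dict
        extras["status"] = status
        self.registry.update(comp_pid, {"extras": extras})

    # ------------------------------------------------------------------ query

    def job_status(self, job_id: str) -> Job:
        job = self._jobs.get(job_id)
        if job is None:
            raise NotFoundError(f"unknown job id: {job_id}")
        return replace(job, output_pids=list(job.output_pids))
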