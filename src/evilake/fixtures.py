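"""Deterministic demonstration registries.

Two generators build registries through the *public* registration and
compute paths only (no store backdoors), so their node counts certify the
whole pipeline:

``generate_hctsa``
    The highly-comparative time-series-analysis (HCTSA) pattern over
    synthetic neonatal vital-sign data: each patient contributes a unique
    raw time-series feature set, a raw-data-analysis computation, and a
    processed time-series file, while the analysis script, clustering
    script, cluster-heatmap-generation computation, and heatmap image are
    shared among all patients.  The heatmap's evidence graph therefore has
    ``3·N + 4`` nodes for ``N`` patients.

``generate_nested_workflow``
    A linear chain of computations, each consuming the previous step's
    output — the deep, workflow-style evidence graph at desk scale.

Payloads are tiny synthetic stand-ins (≤1 KB): seeded heart-rate/SpO2 CSV
rows and a small generated PNG.  Equal ``(n, seed)`` always produce
identical PID sequences and bit-identical serialized registries.
"""

from __future__ import annotations

import io
import statistics
from dataclasses import dataclass
from pathlib import Path
from random import Random
from typing import Optional, Union

from PIL import Image as PILImage

from .commons import Commons
from .errors import ValidationError
from .identifiers import PID
from .model import Draft, EviType
from .store import sha256_hex

_AUTHOR = "NICU Analytics Group"

_RAW_ANALYSIS_SCRIPT = """\
import csv, statistics, sys
from pathlib import Path

data_dir, out_dir = Path(sys.argv[1]), Path(sys.argv[2])
src = sorted(data_dir.glob("*.csv"))[0]
rows = list(csv.DictReader(src.open()))
hr = [float(r["heart_rate"]) for r in rows]
spo2 = [float(r["spo2"]) for r in rows]
with (out_dir / "processed.csv").open("w") as fh:
    fh.write("feature,value\\n")
    fh.write(f"mean_heart_rate,{statistics.fmean(hr):.4f}\\n")
    fh.write(f"mean_spo2,{statistics.fmean(spo2):.4f}\\n")
    fh.write(f"n_samples,{len(rows)}\\n")
"""

_CLUSTERING_SCRIPT = """\
import csv, sys
from pathlib import Path

data_dir, out_dir = Path(sys.argv[1]), Path(sys.argv[2])
values = []
for src in sorted(data_dir.glob("*.csv")):
    for row in csv.DictReader(src.open()):
        if row["feature"] == "mean_heart_rate":
            values.append(float(row["value"]))
# Heatmap rendering is delegated to the service-side imaging step.
(out_dir / "summary.txt").write_text(f"{len(values)} feature sets\\n")
"""


@dataclass(frozen=True)
class PatientArtifacts:
    """PIDs of one patient's registration chain."""

    raw_ts: PID
    raw_comp: PID
    processed_ts: PID


@dataclass(frozen=True)
class HctsaFixture:
    """The registered HCTSA cohort and its key PIDs."""

    n_patients: int
    seed: int
    commons: Commons
    raw_script: PID
    clustering_script: PID
    clustering_computation: PID
    heatmap: PID
    patients: tuple[PatientArtifacts, ...]


@dataclass(frozen=True)
class NestedWorkflowFixture:
    """A linear computation chain: seed dataset plus *depth* steps."""

    depth: int
    seed: int
    commons: Commons
    seed_dataset: PID
    steps: tuple[tuple[PID, PID, PID], ...]  # (software, computation, output)

    @property
    def final_output(self) -> PID:
        return self.steps[-1][2]


def _vitals_csv(rng: Random, patient_tag: str) -> bytes:
    """Eight 10-minute-interval vital-sign samples with seeded noise."""
    lines = ["timestamp,heart_rate,spo2"]
    for i in range(8):
        hr = rng.gauss(140.0, 8.0)
        spo2 = min(100.0, rng.gauss(97.0, 1.5))
        lines.append(f"2019-01-01T{i // 6:02d}:{(i % 6) * 10:02d}:00,{hr:.1f},{spo2:.1f}")
    header = f"# synthetic vitals for {patient_tag}"
    return ("\n".join([header, *lines]) + "\n").encode()


def _analysis_step(data_dir: Path, out_dir: Path) -> None:
    """Per-patient feature extraction: column means of the staged CSV."""
    src = sorted(data_dir.glob("*.csv"))[0]
    hr: list[float] = []
    spo2: list[float] = []
    for line in src.read_text().splitlines():
        if line.startswith("#") or line.startswith("timestamp"):
            continue
        _, h, s = line.split(",")
        hr.append(float(h))
        spo2.append(float(s))
    out = (
        "feature,value\n"
        f"mean_heart_rate,{statistics.fmean(hr):.4f}\n"
        f"mean_spo2,{statistics.fmean(spo2):.4f}\n"
        f"n_samples,{len(hr)}\n"
    )
    (out_dir / "processed.csv").write_text(out)


def _make_heatmap_step(seed: int):
    """Cohort-level step: derive an 8x8 grayscale heatmap PNG from the inputs."""

    def step(data_dir: Path, out_dir: Path) -> None:
        means: list[float] = []
        for src in sorted(data_dir.glob("*.csv")):
            for line in src.read_text().splitlines()[1:]:
                feature, value = line.split(",")
                if feature == "mean_heart_rate":
                    means.append(float(value))
        rng = Random(f"hctsa-heatmap-{seed}")
        base = int(statistics.fmean(means)) % 256 if means else 0
        pixels = [(base + rng.randrange(0, 96)) % 256 for _ in range(64)]
        img = PILImage.new("L", (8, 8))
        img.putdata(pixels)
        buf = io.BytesIO()
        img.save(buf, format="PNG")
        (out_dir / "heatmap.png").write_bytes(buf.getvalue())

    return step


def generate_hctsa(
    n_patients: int,
    seed: int,
    root: Union[str, Path],
    commons: Optional[Commons] = None,
) -> HctsaFixture:
    """Build the HCTSA cohort registry for *n_patients* patients.

    All objects are registered through ``Commons.register`` and
    ``Commons.submit``/``run_job`` with the in-process (noop) executor.
    """
    if n_patients < 1:
        raise ValidationError(f"n_patients must be >= 1, got {n_patients}")
    commons = commons or Commons(root, seed=seed)
    data_rng = Random(f"hctsa-data-{seed}")

    raw_script = commons.register(
        Draft(
            EviType.SOFTWARE,
            "Raw Data Analysis Script",
            description=(
                "Runs the battery of time-series feature algorithms over "
                "10-minute vital-sign intervals"
            ),
            author=_AUTHOR,
        ),
        payload=_RAW_ANALYSIS_SCRIPT.encode(),
        sha256=sha256_hex(_RAW_ANALYSIS_SCRIPT.encode()),
        filename="raw_data_analysis.py",
    ).pid

    clustering_script = commons.register(
        Draft(
            EviType.SOFTWARE,
            "HCTSA Clustering Script",
            description=(
                "Clusters time-series feature algorithms into correlated "
                "groups and renders the cluster heatmap"
            ),
            author=_AUTHOR,
        ),
        payload=_CLUSTERING_SCRIPT.encode(),
        sha256=sha256_hex(_CLUSTERING_SCRIPT.encode()),
        filename="hctsa_clustering.py",
    ).pid

    patients: list[PatientArtifacts] = []
    for i in range(1, n_patients + 1):
        tag = f"UVA_{1000 + i}"
        payload = _vitals_csv(data_rng, tag)
        raw = commons.register(
            Draft(
                EviType.DATASET,
                f"Raw Time Series Feature Set Patient {i}",
                description=f"Continuous heart-rate and SpO2 monitoring for {tag}",
                author=_AUTHOR,
            ),
            payload=payload,
            sha256=sha256_hex(payload),
            filename=f"{tag}_HR.csv",
        ).pid
        job = commons.submit(
            [raw],
            raw_script,
            engine="noop",
            executor=_analysis_step,
            name=f"Raw Data Analysis Patient {i}",
            description="Time-series feature extraction over one patient",
            author=_AUTHOR,
            output_metadata={
                "processed.csv": {
                    "name": f"Processed Time Series Feature Set Patient {i}",
                    "description": f"Extracted features for {tag}",
                    "author": _AUTHOR,
                }
            },
        )
        job = commons.run_job(job)
        if job.state != "completed":  # pragma: no cover - defensive
            raise RuntimeError(f"fixture analysis job failed: {job.log}")
        patients.append(
            PatientArtifacts(
                raw_ts=raw,
                raw_comp=job.computation_pid,
                processed_ts=job.output_pids[0],
            )
        )

    cluster_job = commons.submit(
        [p.processed_ts for p in patients],
        clustering_script,
        engine="noop",
        executor=_make_heatmap_step(seed),
        name="HCTSA Cluster Heatmap Generation",
        description="Clusters feature algorithms across the cohort",
        author=_AUTHOR,
        output_metadata={
            "heatmap.png": {
                "name": "HCTSA Cluster Heatmap",
                "description": "Cluster heatmap of time-series algorithms",
                "author": _AUTHOR,
            }
        },
    )
    cluster_job = commons.run_job(cluster_job)
    if cluster_job.state != "completed":  # pragma: no cover - defensive
        raise RuntimeError(f"fixture clustering job failed: {cluster_job.log}")

    return HctsaFixture(
        n_patients=n_patients,
        seed=seed,
        commons=commons,
        raw_script=raw_script,
        clustering_script=clustering_script,
        clustering_computation=cluster_job.computation_pid,
        heatmap=cluster_job.output_pids[0],
        patients=tuple(patients),
    )


def generate_nested_workflow(
    depth: int,
    seed: int,
    root: Union[str, Path],
    commons: Optional[Commons] = None,
) -> NestedWorkflowFixture:
    """Build a chained workflow: each computation consumes the prior output."""
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    commons = commons or Commons(root, seed=seed)

    seed_payload = b"value\n1\n"
    seed_dataset = commons.register(
        Draft(
            EviType.DATASET,
            "Workflow Seed Dataset",
            description="Initial input of the chained workflow",
            author=_AUTHOR,
        ),
        payload=seed_payload,
        sha256=sha256_hex(seed_payload),
        filename="seed.csv",
    ).pid

    def _step(data_dir: Path, out_dir: Path) -> None:
        src = sorted(data_dir.glob("*.csv"))[0]
        value = int(src.read_text().splitlines()[1])
        (out_dir / "step.csv").write_text(f"value\n{value + 1}\n")

    steps: list[tuple[PID, PID, PID]] = []
    previous = seed_dataset
    for k in range(1, depth + 1):
        script_text = f"# workflow step {k}: increment the running value\n"
        software = commons.register(
            Draft(
                EviType.SOFTWARE,
                f"Workflow Step Software {k}",
                description=f"Step {k} of the chained workflow",
                author=_AUTHOR,
            ),
            payload=script_text.encode(),
            sha256=sha256_hex(script_text.encode()),
            filename=f"step_{k}.py",
        ).pid
        job = commons.submit(
            [previous],
            software,
            engine="noop",
            executor=_step,
            name=f"Workflow Computation {k}",
            author=_AUTHOR,
            output_metadata={
                "step.csv": {
                    "name": f"Workflow Intermediate Dataset {k}",
                    "author": _AUTHOR,
                }
            },
        )
        job = commons.run_job(job)
        if job.state != "completed":  # pragma: no cover - defensive
            raise RuntimeError(f"workflow step {k} failed: {job.log}")
        output = job.output_pids[0]
        steps.append((software, job.computation_pid, output))
        previous = output

    return NestedWorkflowFixture(
        depth=depth,
        seed=seed,
        commons=commons,
        seed_dataset=seed_dataset,
        steps=tuple(steps),
    )
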