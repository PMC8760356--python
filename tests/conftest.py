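"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from evilake import Commons, Draft, EviType, Registry, generate_hctsa
from evilake.model import MetadataRecord


@pytest.fixture()
def commons(tmp_path):
    return Commons(tmp_path / "commons", seed=1)


@pytest.fixture(scope="module")
def hctsa_one(tmp_path_factory):
    """One-patient HCTSA cohort, shared read-only within a module."""
    root = tmp_path_factory.mktemp("hctsa1")
    return generate_hctsa(1, seed=7, root=root)


@pytest.fixture(scope="module")
def hctsa_three(tmp_path_factory):
    root = tmp_path_factory.mktemp("hctsa3")
    return generate_hctsa(3, seed=7, root=root)


# --------------------------------------------------------------------- oracles


def bfs_closure(edge_list, root):
    """Brute-force reachability over a raw (subject, predicate, object) list.

    Independent of both networkx and the package's extraction path.
    """
    adjacency = {}
    for u, _, v in edge_list:
        adjacency.setdefault(u, []).append(v)
    seen = {root}
    stack = [root]
    while stack:
        node = stack.pop()
        for nxt in adjacency.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def support_edge_list(registry):
    """Raw edge list read straight off the stored records."""
    edges = []
    for record in registry.iter_records():
        if record.generated_by is not None:
            edges.append((record.pid, "generatedBy", record.generated_by))
        for d in record.used_datasets:
            edges.append((record.pid, "usedDataset", d))
        for s in record.used_software:
            edges.append((record.pid, "usedSoftware", s))
    return edges


def build_random_dag_registry(seed, max_nodes=50):
    """A randomized valid registry: layered software/datasets/computations.

    Construction guarantees acyclicity (references only point at earlier
    records), so every accepted create exercises the registry's own checks.
    """
    rng = random.Random(seed)
    registry = Registry()
    mint_rng = random.Random(seed + 1)

    software: list = []
    datasets: list = []
    n_nodes = rng.randint(4, max_nodes)
    # Seed layer: a couple of leaves so computations have inputs.
    for i in range(rng.randint(1, 3)):
        pid = registry.mint("59852", "fk4", mint_rng)
        registry.create(
            MetadataRecord(
                pid=pid,
                evi_type=EviType.SOFTWARE,
                name=f"software-{i}",
                created_at=registry.timestamp(),
            )
        )
        software.append(pid)
    for i in range(rng.randint(1, 4)):
        pid = registry.mint("59852", "fk4", mint_rng)
        registry.create(
            MetadataRecord(
                pid=pid,
                evi_type=EviType.DATASET,
                name=f"leaf-dataset-{i}",
                created_at=registry.timestamp(),
            )
        )
        datasets.append(pid)

    step = 0
    while len(registry._records) + 2 <= n_nodes:
        step += 1
        comp_pid = registry.mint("59852", "fk4", mint_rng)
        inputs = rng.sample(datasets, k=min(len(datasets), rng.randint(0, 3)))
        registry.create(
            MetadataRecord(
                pid=comp_pid,
                evi_type=EviType.COMPUTATION,
                name=f"computation-{step}",
                used_datasets=tuple(inputs),
                used_software=(rng.choice(software),),
                created_at=registry.timestamp(),
            )
        )
        for j in range(rng.randint(1, 2)):
            out_pid = registry.mint("59852", "fk4", mint_rng)
            evi_type = EviType.IMAGE if rng.random() < 0.1 else EviType.DATASET
            registry.create(
                MetadataRecord(
                    pid=out_pid,
                    evi_type=evi_type,
                    name=f"output-{step}-{j}",
                    generated_by=comp_pid,
                    created_at=registry.timestamp(),
                )
            )
            if evi_type is EviType.DATASET:
                datasets.append(out_pid)
    return registry


def make_record(
    registry,
    rng,
    evi_type=EviType.DATASET,
    name="record",
    **fields,
):
    """Convenience: mint a PID and build a record for direct registry use."""
    pid = registry.mint("59852", "fk4", rng)
    return MetadataRecord(
        pid=pid,
        evi_type=evi_type,
        name=name,
        created_at=registry.timestamp(),
        **fields,
    )
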