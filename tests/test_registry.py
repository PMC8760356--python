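"""Registry semantics: create/resolve/update, edge index, acyclicity."""

import random

import pytest

from evilake import (
    ConflictError,
    CycleError,
    EviType,
    NotFoundError,
    Registry,
    ValidationError,
)
from conftest import build_random_dag_registry, make_record


@pytest.fixture()
def registry(tmp_path):
    return Registry(tmp_path / "registry.jsonl")


@pytest.fixture()
def rng():
    return random.Random(11)


class TestCreateResolve:
    def test_create_then_resolve_is_identity(self, registry, rng):
        record = make_record(registry, rng, name="vitals")
        registry.create(record)
        assert registry.resolve(record.pid) == record

    def test_duplicate_pid_conflicts_and_leaves_state_unchanged(self, registry, rng):
        record = make_record(registry, rng)
        registry.create(record)
        before = registry.snapshot_bytes()
        with pytest.raises(ConflictError):
            registry.create(record.evolve(name="imposter"))
        assert registry.resolve(record.pid).name == record.name
        assert registry.snapshot_bytes() == before

    def test_dangling_reference_rejected(self, registry, rng):
        ghost = make_record(registry, rng).pid
        record = make_record(
            registry,
            rng,
            evi_type=EviType.COMPUTATION,
            used_software=(ghost,),
        )
        with pytest.raises(ValidationError, match="does not resolve"):
            registry.create(record)

    def test_unknown_pid_not_found(self, registry, rng):
        with pytest.raises(NotFoundError):
            registry.resolve("ark:59852/fk4nothere")

    def test_resolve_document_carries_evidence_graph_link(self, registry, rng):
        record = make_record(registry, rng)
        registry.create(record)
        doc = registry.resolve_document(record.pid)
        assert doc["evidenceGraph"] == f"/evidence-graph/{record.pid}"


class TestAliases:
    def test_alias_resolves_to_canonical_record(self, registry, rng):
        record = make_record(registry, rng, name="canonical")
        registry.create(record)
        alias = registry.mint("59852", "fk4", rng)
        registry.add_alias(alias, record.pid)
        assert registry.resolve(alias) == record
        assert registry.canonical(alias) == record.pid

    def test_alias_never_appears_in_edge_index(self, registry, rng):
        record = make_record(registry, rng)
        registry.create(record)
        alias = registry.mint("59852", "fk4", rng)
        registry.add_alias(alias, record.pid)
        software = make_record(registry, rng, evi_type=EviType.SOFTWARE)
        registry.create(software)
        comp = make_record(
            registry,
            rng,
            evi_type=EviType.COMPUTATION,
            used_datasets=(alias,),  # reference via the alias
            used_software=(software.pid,),
        )
        registry.create(comp)
        targets = {v for _, _, v in registry.edges}
        assert record.pid in targets and alias not in targets


class TestUpdate:
    def test_name_only_update_bumps_version_keeps_edges(self, registry, rng):
        record = make_record(registry, rng, name="v1")
        registry.create(record)
        edges_before = registry.edges
        updated = registry.update(record.pid, {"name": "v2"})
        assert (updated.version, updated.name) == (2, "v2")
        assert registry.edges == edges_before
        assert registry.history(record.pid) == [record]

    def test_adding_used_dataset_adds_one_edge(self, registry, rng):
        ds = make_record(registry, rng)
        sw = make_record(registry, rng, evi_type=EviType.SOFTWARE)
        ds2 = make_record(registry, rng)
        for r in (ds, sw, ds2):
            registry.create(r)
        comp = make_record(
            registry,
            rng,
            evi_type=EviType.COMPUTATION,
            used_datasets=(ds.pid,),
            used_software=(sw.pid,),
        )
        registry.create(comp)
        n_before = len(registry.edges)
        registry.update(comp.pid, {"used_datasets": (ds.pid, ds2.pid)})
        assert len(registry.edges) == n_before + 1

    def test_cycle_via_update_rejected_and_prior_version_resolves(self, registry, rng):
        """The minimal two-computation cycle is unbuildable via create
        (a fresh PID cannot be referenced before it exists) and is rejected
        when attempted via update."""
        sw = make_record(registry, rng, evi_type=EviType.SOFTWARE)
        a = make_record(registry, rng, name="A")
        registry.create(sw)
        registry.create(a)
        c1 = make_record(
            registry, rng, evi_type=EviType.COMPUTATION,
            used_datasets=(a.pid,), used_software=(sw.pid,),
        )
        registry.create(c1)
        b = make_record(registry, rng, name="B", generated_by=c1.pid)
        registry.create(b)
        c2 = make_record(
            registry, rng, evi_type=EviType.COMPUTATION,
            used_datasets=(b.pid,), used_software=(sw.pid,),
        )
        registry.create(c2)
        # Closing the loop: A generatedBy C2 would make A support itself.
        with pytest.raises(CycleError):
            registry.update(a.pid, {"generated_by": c2.pid})
        resolved = registry.resolve(a.pid)
        assert resolved.version == 1 and resolved.generated_by is None
        # Full-state revalidation oracle: rebuilt index matches maintained.
        assert sorted(registry.rebuild_edge_index().edges(keys=True)) == sorted(
            registry.graph_view().edges(keys=True)
        )

    def test_update_unknown_field_rejected(self, registry, rng):
        record = make_record(registry, rng)
        registry.create(record)
        with pytest.raises(ValidationError, match="not patchable"):
            registry.update(record.pid, {"pid": record.pid})


class TestIndexInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_rebuilt_index_equals_maintained_index(self, seed):
        registry = build_random_dag_registry(seed)
        assert sorted(registry.rebuild_edge_index().edges(keys=True)) == sorted(
            registry.graph_view().edges(keys=True)
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_acyclicity_preserved_under_random_operations(self, seed):
        import networkx as nx

        registry = build_random_dag_registry(seed)
        rng = random.Random(seed)
        records = list(registry.iter_records())
        for _ in range(20):  # randomized update attempts, accepted or not
            record = rng.choice(records)
            try:
                if record.evi_type is EviType.COMPUTATION:
                    extra = rng.choice(records)
                    registry.update(
                        record.pid,
                        {"used_datasets": record.used_datasets + (extra.pid,)},
                    )
                else:
                    comp = rng.choice(
                        [
                            r
                            for r in records
                            if r.evi_type is EviType.COMPUTATION
                        ]
                        or records
                    )
                    registry.update(record.pid, {"generated_by": comp.pid})
            except (ValidationError, CycleError, IndexError):
                pass
            assert nx.is_directed_acyclic_graph(registry.graph_view())
            records = list(registry.iter_records())


class TestPersistence:
    def test_reload_reproduces_records_and_index(self, tmp_path, rng):
        path = tmp_path / "registry.jsonl"
        registry = Registry(path)
        ds = make_record(registry, rng)
        sw = make_record(registry, rng, evi_type=EviType.SOFTWARE)
        registry.create(ds)
        registry.create(sw)
        comp = make_record(
            registry,
            rng,
            evi_type=EviType.COMPUTATION,
            used_datasets=(ds.pid,),
            used_software=(sw.pid,),
        )
        registry.create(comp)
        registry.update(comp.pid, {"description": "second thoughts"})

        reloaded = Registry(path)
        assert list(reloaded.iter_records()) == list(registry.iter_records())
        assert reloaded.edges == registry.edges
        assert reloaded.snapshot_bytes() == registry.snapshot_bytes()
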