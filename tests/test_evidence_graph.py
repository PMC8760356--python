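"""Evidence-graph extraction, challenge propagation, and exports."""

import json
import re

import pytest

from evilake import (
    Draft,
    EviType,
    NotFoundError,
    deserialize_graph,
    extract,
    generate_hctsa,
    serialize_graph,
    sha256_hex,
    to_cytoscape,
    to_dot,
    undermined,
)
from conftest import bfs_closure, build_random_dag_registry, support_edge_list


class TestExtract:
    def test_single_patient_heatmap_closure_is_the_seven_node_chain(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.heatmap)
        assert len(graph) == 7
        assert len(graph.edges) == 6
        expected = {
            hctsa_one.heatmap,
            hctsa_one.clustering_computation,
            hctsa_one.clustering_script,
            hctsa_one.patients[0].processed_ts,
            hctsa_one.patients[0].raw_comp,
            hctsa_one.patients[0].raw_ts,
            hctsa_one.raw_script,
        }
        assert graph.node_set == expected

    def test_leaf_dataset_closure_is_itself(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.patients[0].raw_ts)
        assert len(graph) == 1 and graph.edges == ()

    def test_unresolvable_root_not_found(self, commons):
        with pytest.raises(NotFoundError):
            commons.evidence_graph("ark:59852/fk4missing1")

    def test_node_order_is_breadth_first_then_lexicographic(self, hctsa_three):
        graph = hctsa_three.commons.evidence_graph(hctsa_three.heatmap)
        pids = graph.node_pids
        assert pids[0] == hctsa_three.heatmap
        assert pids[1] == hctsa_three.clustering_computation
        # level 2: the clustering script and 3 processed datasets, sorted
        level2 = pids[2:6]
        assert level2 == sorted(level2, key=str)

    def test_monotonicity_downstream_use_never_changes_closure(self, tmp_path):
        fixture = generate_hctsa(1, seed=3, root=tmp_path / "m")
        commons = fixture.commons
        target = fixture.patients[0].processed_ts
        before = commons.evidence_graph(target)
        # a brand-new computation consuming `target` looks forward only
        job = commons.run_job(
            commons.submit(
                [target],
                fixture.clustering_script,
                engine="noop",
                executor=lambda d, o: (o / "again.csv").write_text("x\n"),
            )
        )
        assert job.state == "completed"
        assert commons.evidence_graph(target) == before

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_randomized_registries(self, seed):
        """extract() equals brute-force BFS over the raw edge list for
        every root of a randomized ≤50-node DAG registry."""
        registry = build_random_dag_registry(seed)
        edge_list = support_edge_list(registry)
        for record in registry.iter_records():
            graph = extract(registry, record.pid)
            assert graph.node_set == bfs_closure(edge_list, record.pid)


class TestSerialization:
    def test_single_patient_document_has_seven_graph_entries(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.heatmap)
        doc = serialize_graph(graph)
        assert len(doc["@graph"]) == 7
        assert doc["root"] == str(hctsa_one.heatmap)
        assert "@context" in doc

    def test_serialize_deserialize_identity(self, hctsa_three):
        graph = hctsa_three.commons.evidence_graph(hctsa_three.heatmap)
        doc = json.loads(json.dumps(serialize_graph(graph)))  # through JSON
        assert deserialize_graph(doc) == graph

    def test_leaf_serializes_to_single_entry(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.patients[0].raw_ts)
        assert len(serialize_graph(graph)["@graph"]) == 1


class TestChallenges:
    def test_challenge_resolvable_by_own_pid(self, tmp_path):
        fixture = generate_hctsa(1, seed=5, root=tmp_path / "c")
        commons = fixture.commons
        ch = commons.challenge(
            fixture.raw_script, "error-in-algorithm", "windowing bug"
        )
        resolved = commons.resolve(ch.pid)
        assert resolved.target == fixture.raw_script
        assert resolved.category == "error-in-algorithm"

    def test_challenge_unknown_target_not_found(self, commons):
        with pytest.raises(NotFoundError):
            commons.challenge("ark:59852/fk4missing1", "other")

    def test_two_challenges_on_one_target_are_independent(self, tmp_path):
        fixture = generate_hctsa(1, seed=5, root=tmp_path / "c2")
        commons = fixture.commons
        a = commons.challenge(fixture.raw_script, "retraction")
        b = commons.challenge(fixture.raw_script, "disputed-method")
        assert a.pid != b.pid
        assert {c.pid for c in commons.registry.iter_challenges()} == {a.pid, b.pid}

    def test_challenge_adds_no_support_edges(self, tmp_path):
        fixture = generate_hctsa(1, seed=5, root=tmp_path / "c3")
        commons = fixture.commons
        edges_before = commons.registry.edges
        commons.challenge(fixture.raw_script, "other")
        assert commons.registry.edges == edges_before


class TestUndermined:
    def test_challenged_script_undermines_heatmap_with_path(self, tmp_path):
        fixture = generate_hctsa(1, seed=9, root=tmp_path / "u")
        commons = fixture.commons
        ch = commons.challenge(fixture.raw_script, "error-in-algorithm")
        findings = commons.undermined(fixture.heatmap)
        assert len(findings) == 1
        assert findings[0].challenge.pid == ch.pid
        path = findings[0].path
        assert path[0] == fixture.heatmap and path[-1] == fixture.raw_script
        # the path walks the support chain through both computations
        assert path == (
            fixture.heatmap,
            fixture.clustering_computation,
            fixture.patients[0].processed_ts,
            fixture.patients[0].raw_comp,
            fixture.raw_script,
        )
        # the raw dataset's own closure does not contain the script
        assert commons.undermined(fixture.patients[0].raw_ts) == []

    def test_challenged_patient_undermines_heatmap_not_other_patients(self, tmp_path):
        fixture = generate_hctsa(3, seed=9, root=tmp_path / "u3")
        commons = fixture.commons
        commons.challenge(fixture.patients[0].raw_ts, "contaminated-input")
        assert len(commons.undermined(fixture.heatmap)) == 1
        assert commons.undermined(fixture.patients[1].processed_ts) == []
        assert len(commons.undermined(fixture.patients[0].processed_ts)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_undermined_equals_definitional_set(self, seed):
        """undermined(e) is exactly the challenges whose target is in
        extract(e)'s node set."""
        import random

        registry = build_random_dag_registry(seed)
        from evilake.graph import challenge as make_challenge

        rng = random.Random(seed + 100)
        records = list(registry.iter_records())
        challenged = rng.sample(records, k=min(3, len(records)))
        for target in challenged:
            make_challenge(
                registry, rng, "59852", "fk4", target.pid, "other"
            )
        edge_list = support_edge_list(registry)
        for record in records:
            closure = bfs_closure(edge_list, record.pid)
            expected = {
                ch.pid
                for ch in registry.iter_challenges()
                if ch.target in closure
            }
            got = {f.challenge.pid for f in undermined(registry, record.pid)}
            assert got == expected


class TestVisualExports:
    def test_cytoscape_counts_match_fixture_graph(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.heatmap)
        doc = to_cytoscape(graph)
        assert len(doc["elements"]["nodes"]) == 7
        assert len(doc["elements"]["edges"]) == 6
        node = doc["elements"]["nodes"][0]["data"]
        assert set(node) == {"id", "label", "evi_type"}
        edge = doc["elements"]["edges"][0]["data"]
        assert {"source", "target", "predicate"} <= set(edge)

    def test_dot_output_is_grammatical(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.heatmap)
        dot = to_dot(graph)
        _check_dot(dot, expected_nodes=7, expected_edges=6)

    def test_single_node_dot_has_no_edge_statements(self, hctsa_one):
        graph = hctsa_one.commons.evidence_graph(hctsa_one.patients[0].raw_ts)
        _check_dot(to_dot(graph), expected_nodes=1, expected_edges=0)


_NODE_STMT = re.compile(r'^\s*"[^"]+"\s*\[[^\]]*\];$')
_EDGE_STMT = re.compile(r'^\s*"[^"]+"\s*->\s*"[^"]+"\s*\[[^\]]*\];$')
_ATTR_STMT = re.compile(r"^\s*\w+=\w+;$")


def _check_dot(dot: str, expected_nodes: int, expected_edges: int) -> None:
    """Minimal structural DOT grammar check, independent of the writer."""
    lines = dot.strip().splitlines()
    assert lines[0].startswith("digraph") and lines[0].endswith("{")
    assert lines[-1] == "}"
    nodes = edges = 0
    for line in lines[1:-1]:
        if _EDGE_STMT.match(line):
            edges += 1
        elif _NODE_STMT.match(line):
            nodes += 1
        else:
            assert _ATTR_STMT.match(line), f"unparseable DOT line: {line!r}"
    assert (nodes, edges) == (expected_nodes, expected_edges)
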