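"""Evidence-graph extraction, challenge reasoning, and export.

The evidence graph of a PID is the exact reachability closure of that PID
along the support predicates ``generatedBy``, ``usedDataset`` and
``usedSoftware``: every dataset, script and computation that transitively
supports the result, and nothing else.  Because the registry keeps the edge
relation acyclic, traversal at unbounded depth always terminates.

Challenge semantics are simple reverse reachability: a result is undermined
if and only if some node in its support closure carries a challenge.
Richer argumentation semantics (defeat, reinstatement) are deliberately not
modeled.

Node order is breadth-first from the root with lexicographic PID order
within each level; edges are sorted by (subject, predicate, object).  All
serializations are therefore deterministic, which keeps golden-file tests
stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional, Union

from .errors import NotFoundError
from .identifiers import PID, as_pid, parse_pid
from .model import (
    EVI_CONTEXT,
    ChallengeRecord,
    EviType,
    MetadataRecord,
)
from .registry import Registry

Edge = tuple[PID, str, PID]


@dataclass(frozen=True)
class EvidenceGraph:
    """The support closure of one root PID."""

    root: PID
    nodes: tuple[tuple[PID, EviType, str], ...]  # (pid, type, name), ordered
    edges: tuple[Edge, ...]

    @property
    def node_pids(self) -> list[PID]:
        return [pid for pid, _, _ in self.nodes]

    @property
    def node_set(self) -> frozenset[PID]:
        return frozenset(pid for pid, _, _ in self.nodes)

    def type_census(self) -> dict[str, int]:
        """Count of nodes per EVI type, e.g. ``{"Dataset": 11994, ...}``."""
        census: dict[str, int] = {}
        for _, evi_type, _ in self.nodes:
            census[evi_type.value] = census.get(evi_type.value, 0) + 1
        return census

    def __len__(self) -> int:
        return len(self.nodes)


def extract(
    registry: Registry,
    root: Union[PID, str],
    include_parameters: bool = False,
) -> EvidenceGraph:
    """Compute the support closure of *root*.

    From each entity the traversal follows its ``generatedBy`` computation;
    from each computation, its ``usedDataset`` and ``usedSoftware`` targets
    (plus ``parameters`` when *include_parameters* is set — runtime
    parameters are linked to computations but stay out of evidence graphs
    by default).
    """
    root = registry.canonical(as_pid(root))
    root_record = registry.resolve(root)
    if isinstance(root_record, ChallengeRecord):
        raise NotFoundError(f"{root} is a challenge, not an evidence node")

    nodes: list[tuple[PID, EviType, str]] = []
    edges: set[Edge] = set()
    seen: set[PID] = {root}
    frontier = [root]
    while frontier:
        next_frontier: list[PID] = []
        for pid in frontier:
            record = registry.resolve(pid)
            nodes.append((pid, record.evi_type, record.name))
            for predicate, target in _support_links(
                registry, record, include_parameters
            ):
                edges.add((pid, predicate, target))
                if target not in seen:
                    seen.add(target)
                    next_frontier.append(target)
        frontier = sorted(set(next_frontier), key=str)
    return EvidenceGraph(
        root=root,
        nodes=tuple(nodes),
        edges=tuple(sorted(edges, key=lambda e: (str(e[0]), e[1], str(e[2])))),
    )


def _support_links(
    registry: Registry, record: MetadataRecord, include_parameters: bool
) -> list[tuple[str, PID]]:
    links: list[tuple[str, PID]] = []
    if record.generated_by is not None:
        links.append(("generatedBy", registry.canonical(record.generated_by)))
    links.extend(
        ("usedDataset", registry.canonical(p)) for p in record.used_datasets
    )
    links.extend(
        ("usedSoftware", registry.canonical(p)) for p in record.used_software
    )
    if include_parameters and record.parameters is not None:
        links.append(("parameters", registry.canonical(record.parameters)))
    return links


# ------------------------------------------------------------- serialization


def serialize_graph(graph: EvidenceGraph) -> dict[str, Any]:
    """Serialize to a JSON-LD document with an ``@graph`` node array.

    Each node document embeds its outgoing support edges; deserializing
    with :func:`deserialize_graph` reproduces the graph exactly.
    """
    by_subject: dict[PID, dict[str, list[PID]]] = {}
    for u, p, v in graph.edges:
        by_subject.setdefault(u, {}).setdefault(p, []).append(v)
    entries = []
    for pid, evi_type, name in graph.nodes:
        entry: dict[str, Any] = {
            "@id": str(pid),
            "@type": f"evi:{evi_type.value}",
            "name": name,
        }
        outgoing = by_subject.get(pid, {})
        for predicate in ("generatedBy", "usedDataset", "usedSoftware", "parameters"):
            if predicate not in outgoing:
                continue
            values = sorted(str(v) for v in outgoing[predicate])
            if predicate == "generatedBy":
                entry[predicate] = values[0]
            else:
                entry[predicate] = values
        entries.append(entry)
    return {
        "@context": EVI_CONTEXT,
        "root": str(graph.root),
        "@graph": entries,
    }


def deserialize_graph(document: dict[str, Any]) -> EvidenceGraph:
    """Inverse of :func:`serialize_graph`."""
    nodes: list[tuple[PID, EviType, str]] = []
    edges: list[Edge] = []
    for entry in document["@graph"]:
        pid = parse_pid(entry["@id"])
        type_name = entry["@type"].split(":", 1)[-1].split("#")[-1]
        nodes.append((pid, EviType(type_name), entry.get("name", "")))
        if "generatedBy" in entry:
            edges.append((pid, "generatedBy", parse_pid(entry["generatedBy"])))
        for predicate in ("usedDataset", "usedSoftware", "parameters"):
            for target in entry.get(predicate, []):
                edges.append((pid, predicate, parse_pid(target)))
    return EvidenceGraph(
        root=parse_pid(document["root"]),
        nodes=tuple(nodes),
        edges=tuple(sorted(edges, key=lambda e: (str(e[0]), e[1], str(e[2])))),
    )


# ----------------------------------------------------------------- challenge


def challenge(
    registry: Registry,
    rng,
    naan: str,
    shoulder: str,
    target: Union[PID, str],
    category: str,
    description: str = "",
) -> ChallengeRecord:
    """Mint and persist a challenge against *target*.

    Support edges are untouched: challenges affect reasoning (via
    :func:`undermined`), not graph structure.
    """
    target = registry.canonical(as_pid(target))
    if registry.get(target) is None:
        raise NotFoundError(f"unknown PID: {target}")
    record = ChallengeRecord(
        pid=registry.mint(naan, shoulder, rng),
        target=target,
        category=category,
        description=description,
        created_at=registry.timestamp(),
    )
    registry.register_challenge(record)
    return record


@dataclass(frozen=True)
class UnderminedFinding:
    """One challenge affecting an entity, with a support path as evidence."""

    challenge: ChallengeRecord
    path: tuple[PID, ...]  # entity -> ... -> challenged node


def undermined(
    registry: Registry,
    entity: Union[PID, str],
    include_parameters: bool = False,
) -> list[UnderminedFinding]:
    """All challenges whose target lies in *entity*'s support closure.

    An entity is undermined iff a challenged node transitively supports it.
    Each finding carries one support path from the entity to the challenged
    node.
    """
    graph = extract(registry, entity, include_parameters=include_parameters)
    closure = graph.node_set
    adjacency: dict[PID, list[PID]] = {}
    for u, _, v in graph.edges:
        adjacency.setdefault(u, []).append(v)
    findings = []
    for ch in registry.iter_challenges():
        target = registry.canonical(ch.target)
        if target in closure:
            findings.append(
                UnderminedFinding(
                    challenge=ch,
                    path=tuple(_shortest_path(adjacency, graph.root, target)),
                )
            )
    return findings


def _shortest_path(
    adjacency: dict[PID, list[PID]], source: PID, target: PID
) -> list[PID]:
    if source == target:
        return [source]
    parent: dict[PID, PID] = {}
    frontier = [source]
    seen = {source}
    while frontier:
        nxt = []
        for node in frontier:
            for neighbor in sorted(adjacency.get(node, []), key=str):
                if neighbor in seen:
                    continue
                seen.add(neighbor)
                parent[neighbor] = node
                if neighbor == target:
                    path = [target]
                    while path[-1] != source:
                        path.append(parent[path[-1]])
                    return list(reversed(path))
                nxt.append(neighbor)
        frontier = nxt
    raise NotFoundError(f"no support path from {source} to {target}")


# --------------------------------------------------------------- visual form

_DOT_STYLE = {
    EviType.DATASET: ("box", "lightblue"),
    EviType.SOFTWARE: ("note", "lightyellow"),
    EviType.COMPUTATION: ("ellipse", "lightgrey"),
    EviType.IMAGE: ("box3d", "lightpink"),
    EviType.CHALLENGE: ("octagon", "tomato"),
}


def to_cytoscape(graph: EvidenceGraph) -> dict[str, Any]:
    """Cytoscape-JSON elements: nodes carry id/label/type, edges a predicate."""
    nodes = [
        {
            "data": {
                "id": str(pid),
                "label": name,
                "evi_type": evi_type.value,
            }
        }
        for pid, evi_type, name in graph.nodes
    ]
    edges = [
        {
            "data": {
                "id": f"e{i}",
                "source": str(u),
                "target": str(v),
                "predicate": p,
            }
        }
        for i, (u, p, v) in enumerate(graph.edges)
    ]
    return {"elements": {"nodes": nodes, "edges": edges}}


def to_dot(graph: EvidenceGraph) -> str:
    """Graphviz DOT with type-keyed node styling."""
    lines = ["digraph evidence {", "  rankdir=BT;"]
    for pid, evi_type, name in graph.nodes:
        shape, color = _DOT_STYLE[evi_type]
        label = f"{name}\\n{evi_type.value}\\n{pid}".replace('"', r"\"")
        lines.append(
            f'  "{pid}" [label="{label}", shape={shape}, '
            f'style=filled, fillcolor="{color}"];'
        )
    for u, p, v in graph.edges:
        lines.append(f'  "{u}" -> "{v}" [label="{p}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
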