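"""EVI metadata record types and their JSON-LD serialization.

The evidence (EVI) vocabulary extends W3C PROV: Datasets, Software and
Images are PROV Entities, Computations are PROV Activities.  A record's
provenance fields induce typed, directed support edges:

* ``generatedBy``  — an entity points at the computation that produced it,
* ``usedDataset``  — a computation points at each input dataset,
* ``usedSoftware`` — a computation points at the script/software it ran.

A Challenge is an assertion that some node's correctness is disputed; it is
linked to its target but never participates in support edges.

Records serialize to flat JSON-LD 1.1 documents carrying a bundled static
``@context`` (no network fetch).  Serialization is lossless over the
supported vocabulary; unknown keys survive round-trips in an ``extras`` bag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Callable, Optional

from .errors import PIDParseError, ValidationError
from .identifiers import PID, as_pid, parse_pid

EVI_NAMESPACE = "https://w3id.org/EVI#"
PROV_NAMESPACE = "http://www.w3.org/ns/prov#"

#: Static JSON-LD context emitted with every document.  EVI entity types are
#: aligned with PROV (Dataset/Software/Image ⊑ prov:Entity, Computation ⊑
#: prov:Activity) in the bundled context document; authors stay literals.
EVI_CONTEXT: dict[str, Any] = {
    "@vocab": EVI_NAMESPACE,
    "evi": EVI_NAMESPACE,
    "prov": PROV_NAMESPACE,
    "usedDataset": {"@id": "evi:usedDataset", "@type": "@id", "@container": "@list"},
    "usedSoftware": {"@id": "evi:usedSoftware", "@type": "@id", "@container": "@list"},
    "generatedBy": {"@id": "evi:generatedBy", "@type": "@id"},
    "parameters": {"@id": "evi:parameters", "@type": "@id"},
    "challenges": {"@id": "evi:challenges", "@type": "@id"},
    "evidenceGraph": {"@id": "evi:evidenceGraph", "@type": "@id"},
}


class EviType(str, Enum):
    """The node types appearing in evidence graphs, plus Challenge."""

    DATASET = "Dataset"
    SOFTWARE = "Software"
    COMPUTATION = "Computation"
    IMAGE = "Image"
    CHALLENGE = "Challenge"


#: Types allowed to carry a ``generatedBy`` link (computation outputs).
GENERATED_TYPES = frozenset({EviType.DATASET, EviType.IMAGE})

CHALLENGE_CATEGORIES = frozenset(
    {
        "retraction",
        "error-in-algorithm",
        "contaminated-input",
        "disputed-method",
        "other",
    }
)

_SHA256_RE = re.compile(r"^[0-9a-f]{64}$")

# Keys owned by the vocabulary; extras may not shadow them.
_RESERVED_KEYS = frozenset(
    {
        "@context",
        "@id",
        "@type",
        "name",
        "description",
        "author",
        "checksum",
        "contentLocation",
        "usedDataset",
        "usedSoftware",
        "generatedBy",
        "parameters",
        "dateCreated",
        "version",
        "evidenceGraph",
        "challenges",
        "category",
    }
)


@dataclass(frozen=True)
class MetadataRecord:
    """A registered object's full JSON-LD-serializable description."""

    pid: PID
    evi_type: EviType
    name: str
    description: str = ""
    author: str = ""
    checksum: Optional[str] = None  # sha256 hex digest
    content_location: Optional[str] = None
    used_datasets: tuple[PID, ...] = ()
    used_software: tuple[PID, ...] = ()
    generated_by: Optional[PID] = None
    parameters: Optional[PID] = None
    created_at: str = ""
    version: int = 1
    extras: tuple[tuple[str, Any], ...] = ()

    @property
    def extras_dict(self) -> dict[str, Any]:
        return dict(self.extras)

    def evolve(self, **changes: Any) -> "MetadataRecord":
        if "extras" in changes and isinstance(changes["extras"], dict):
            changes["extras"] = tuple(sorted(changes["extras"].items()))
        return replace(self, **changes)


@dataclass(frozen=True)
class Draft:
    """A metadata record before registration assigns pid and location."""

    evi_type: EviType
    name: str
    description: str = ""
    author: str = ""
    used_datasets: tuple[PID, ...] = ()
    used_software: tuple[PID, ...] = ()
    generated_by: Optional[PID] = None
    parameters: Optional[PID] = None
    extras: tuple[tuple[str, Any], ...] = ()

    def to_record(
        self,
        pid: PID,
        *,
        checksum: Optional[str] = None,
        content_location: Optional[str] = None,
        created_at: str = "",
    ) -> MetadataRecord:
        return MetadataRecord(
            pid=pid,
            evi_type=self.evi_type,
            name=self.name,
            description=self.description,
            author=self.author,
            checksum=checksum,
            content_location=content_location,
            used_datasets=tuple(as_pid(p) for p in self.used_datasets),
            used_software=tuple(as_pid(p) for p in self.used_software),
            generated_by=as_pid(self.generated_by) if self.generated_by else None,
            parameters=as_pid(self.parameters) if self.parameters else None,
            created_at=created_at,
            extras=tuple(sorted(dict(self.extras).items())),
        )


@dataclass(frozen=True)
class ChallengeRecord:
    """An assertion that a node's correctness is disputed.

    Challenges hang off their target but never add support edges, so they
    undermine results only through the reverse-reachability semantics in
    :mod:`evilake.graph`.
    """

    pid: PID
    target: PID
    category: str
    description: str = ""
    created_at: str = ""

    def __post_init__(self) -> None:
        if self.category not in CHALLENGE_CATEGORIES:
            raise ValidationError(
                f"unknown challenge category {self.category!r}; "
                f"expected one of {sorted(CHALLENGE_CATEGORIES)}"
            )


def to_jsonld(record: MetadataRecord) -> dict[str, Any]:
    """Serialize a record to a flat JSON-LD document.

    Null provenance fields are omitted entirely; list order is preserved.
    Raises :class:`ValidationError` if the record fails type-level checks.
    """
    violations = validate_record(record)
    if violations:
        raise ValidationError(violations)
    doc: dict[str, Any] = {
        "@context": EVI_CONTEXT,
        "@id": str(record.pid),
        "@type": f"evi:{record.evi_type.value}",
        "name": record.name,
        "description": record.description,
        "author": record.author,
        "version": record.version,
    }
    if record.checksum is not None:
        doc["checksum"] = f"sha256:{record.checksum}"
    if record.content_location is not None:
        doc["contentLocation"] = record.content_location
    if record.used_datasets:
        doc["usedDataset"] = [str(p) for p in record.used_datasets]
    if record.used_software:
        doc["usedSoftware"] = [str(p) for p in record.used_software]
    if record.generated_by is not None:
        doc["generatedBy"] = str(record.generated_by)
    if record.parameters is not None:
        doc["parameters"] = str(record.parameters)
    if record.created_at:
        doc["dateCreated"] = record.created_at
    for key, value in record.extras:
        doc[key] = value
    return doc


def from_jsonld(document: dict[str, Any]) -> MetadataRecord:
    """Parse a JSON-LD document back into a :class:`MetadataRecord`.

    Inverse of :func:`to_jsonld` on the supported vocabulary; unknown keys
    are preserved in the record's ``extras`` bag.
    """
    if "@id" not in document:
        raise PIDParseError("document is missing @id")
    if "@type" not in document:
        raise PIDParseError("document is missing @type")
    type_value = document["@type"]
    evi_type = _resolve_type(type_value)
    checksum = document.get("checksum")
    if checksum is not None:
        if not isinstance(checksum, str) or not checksum.startswith("sha256:"):
            raise ValidationError(f"unsupported checksum form {checksum!r}")
        checksum = checksum[len("sha256:"):]
    extras = {
        k: v
        for k, v in document.items()
        if k not in _RESERVED_KEYS
    }
    return MetadataRecord(
        pid=parse_pid(document["@id"]),
        evi_type=evi_type,
        name=document.get("name", ""),
        description=document.get("description", ""),
        author=document.get("author", ""),
        checksum=checksum,
        content_location=document.get("contentLocation"),
        used_datasets=tuple(parse_pid(p) for p in document.get("usedDataset", [])),
        used_software=tuple(parse_pid(p) for p in document.get("usedSoftware", [])),
        generated_by=(
            parse_pid(document["generatedBy"]) if "generatedBy" in document else None
        ),
        parameters=(
            parse_pid(document["parameters"]) if "parameters" in document else None
        ),
        created_at=document.get("dateCreated", ""),
        version=document.get("version", 1),
        extras=tuple(sorted(extras.items())),
    )


def _resolve_type(type_value: str) -> EviType:
    """Map an ``@type`` value (curie or full IRI) to an :class:`EviType`."""
    if not isinstance(type_value, str):
        raise PIDParseError(f"@type must be a string, got {type_value!r}")
    local = type_value
    for prefix in (f"{EVI_NAMESPACE}", "evi:"):
        if local.startswith(prefix):
            local = local[len(prefix):]
            break
    try:
        return EviType(local)
    except ValueError:
        raise PIDParseError(f"unresolvable @type IRI {type_value!r}") from None


Resolver = Callable[[PID], Optional[MetadataRecord]]


def validate_record(
    record: MetadataRecord, resolver: Optional[Resolver] = None
) -> list[str]:
    """Return the list of structural violations for *record* (empty = valid).

    With a *resolver*, referenced PIDs must resolve; without one only
    type-level constraints are checked.  Violations are returned, never
    raised.
    """
    v: list[str] = []
    if record.evi_type is EviType.CHALLENGE:
        v.append("Challenge assertions use ChallengeRecord, not MetadataRecord")
    if not record.name:
        v.append("record requires a non-empty name")
    if record.version < 1:
        v.append(f"version must be >= 1, got {record.version}")
    if record.checksum is not None and not _SHA256_RE.match(record.checksum):
        v.append(f"checksum is not a sha256 hex digest: {record.checksum!r}")
    for key, _ in record.extras:
        if key in _RESERVED_KEYS or key.startswith("@"):
            v.append(f"extras key shadows a vocabulary term: {key!r}")

    is_computation = record.evi_type is EviType.COMPUTATION
    if is_computation:
        if not record.used_software:
            v.append("Computation requires usedSoftware")
        if record.generated_by is not None:
            v.append("Computation may not carry generatedBy")
    else:
        if record.used_datasets or record.used_software:
            v.append(f"{record.evi_type.value} may not carry usedDataset/usedSoftware")
        if record.parameters is not None:
            v.append(f"{record.evi_type.value} may not carry parameters")
        if record.generated_by is not None and record.evi_type not in GENERATED_TYPES:
            v.append(f"{record.evi_type.value} may not carry generatedBy")

    referenced = list(record.used_datasets) + list(record.used_software)
    if record.generated_by is not None:
        referenced.append(record.generated_by)
    if record.parameters is not None:
        referenced.append(record.parameters)
    for ref in referenced:
        if ref == record.pid:
            v.append(f"self-support cycle: {record.pid} references itself")
        elif resolver is not None and resolver(ref) is None:
            v.append(f"referenced PID does not resolve: {ref}")
    if (
        resolver is not None
        and record.generated_by is not None
        and record.generated_by != record.pid
    ):
        producer = resolver(record.generated_by)
        if producer is not None and producer.evi_type is not EviType.COMPUTATION:
            v.append(
                f"generatedBy must reference a Computation, "
                f"not {producer.evi_type.value}"
            )
    return v


def challenge_to_jsonld(challenge: ChallengeRecord) -> dict[str, Any]:
    doc = {
        "@context": EVI_CONTEXT,
        "@id": str(challenge.pid),
        "@type": "evi:Challenge",
        "challenges": str(challenge.target),
        "category": challenge.category,
        "description": challenge.description,
    }
    if challenge.created_at:
        doc["dateCreated"] = challenge.created_at
    return doc


def challenge_from_jsonld(document: dict[str, Any]) -> ChallengeRecord:
    if _resolve_type(document.get("@type", "")) is not EviType.CHALLENGE:
        raise PIDParseError(f"not a Challenge document: {document.get('@type')!r}")
    return ChallengeRecord(
        pid=parse_pid(document["@id"]),
        target=parse_pid(document["challenges"]),
        category=document["category"],
        description=document.get("description", ""),
        created_at=document.get("dateCreated", ""),
    )
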