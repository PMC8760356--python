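"""Exact-substring search over metadata literals.

Case-sensitive contiguous substring matching over every record's literal
fields (name, description, author, and string-valued extras), in insertion
order — the behaviour of a literal scan, with no stemming or ranking.
Tombstoned records keep their metadata and therefore remain findable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .identifiers import PID
from .registry import Registry


@dataclass(frozen=True)
class SearchResult:
    query: str
    pids: tuple[PID, ...]
    matched_fields: tuple[tuple[PID, tuple[str, ...]], ...]

    @property
    def matched_fields_dict(self) -> dict[PID, tuple[str, ...]]:
        return dict(self.matched_fields)


def literal_fields(record) -> dict[str, str]:
    """The searchable literal fields of a record, field name → value."""
    fields = {
        "name": record.name,
        "description": record.description,
        "author": record.author,
    }
    for key, value in record.extras:
        if isinstance(value, str):
            fields[key] = value
    return {k: v for k, v in fields.items() if v}


def search_literals(registry: Registry, query: str) -> SearchResult:
    """Return every PID whose record contains *query* in a literal field."""
    if not query:
        raise ValidationError("search query must be non-empty")
    pids: list[PID] = []
    matches: list[tuple[PID, tuple[str, ...]]] = []
    for record in registry.iter_records():
        hit_fields = tuple(
            name for name, value in literal_fields(record).items() if query in value
        )
        if hit_fields:
            pids.append(record.pid)
            matches.append((record.pid, hit_fields))
    return SearchResult(
        query=query, pids=tuple(pids), matched_fields=tuple(matches)
    )
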