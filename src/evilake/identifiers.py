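"""ARK-form persistent identifiers (PIDs).

Every object in an evilake commons — dataset, software, computation, image,
challenge — is keyed by an Archival Resource Key of the form::

    ark:{naan}/{shoulder}{blade}

where *naan* is a five-digit Name Assigning Authority Number, *shoulder* is a
short namespace prefix that by convention ends in a digit (the "first-digit"
rule), and *blade* is the unique suffix.  Blades are drawn from the
betanumeric alphabet (digits plus consonants) so minted names never spell
accidental words.

Both the modern ``ark:naan/name`` spelling and the legacy ``ark:/naan/name``
spelling are accepted on input; output is always the slashless form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from random import Random

from .errors import PIDParseError, ValidationError

#: Betanumeric alphabet: digits plus consonants, no vowels.
BETANUMERIC = "0123456789bcdfghjkmnpqrstvwxz"

#: Default blade length for minted identifiers.
DEFAULT_BLADE_LENGTH = 8

_NAAN_RE = re.compile(r"^\d{5}$")
_ARK_RE = re.compile(r"^ark:/?(?P<naan>[^/]+)/(?P<name>.+)$")
# First-digit convention: the shoulder is everything up to and including the
# first digit of the name; if the name has no digit the shoulder is empty.
_SHOULDER_RE = re.compile(r"^(?P<shoulder>[^\d]*\d)(?P<blade>.*)$")


@dataclass(frozen=True, order=True)
class PID:
    """An ARK-form persistent identifier, split into its components."""

    naan: str
    shoulder: str
    blade: str

    def __post_init__(self) -> None:
        if not _NAAN_RE.match(self.naan):
            raise ValidationError(
                f"NAAN must be exactly 5 decimal digits, got {self.naan!r}"
            )
        if not (self.shoulder + self.blade):
            raise ValidationError("ARK name (shoulder+blade) must be non-empty")

    @property
    def name(self) -> str:
        """The ARK name: shoulder and blade concatenated."""
        return self.shoulder + self.blade

    def __str__(self) -> str:
        return f"ark:{self.naan}/{self.name}"


def mint_pid(
    naan: str,
    shoulder: str,
    rng: Random,
    blade_length: int = DEFAULT_BLADE_LENGTH,
) -> PID:
    """Mint a fresh PID with a random betanumeric blade.

    The caller supplies the random source so identifier sequences are
    reproducible under a fixed seed.  Uniqueness against an existing registry
    is the registry's responsibility (it re-mints on the astronomically rare
    collision).
    """
    if not isinstance(naan, str) or not _NAAN_RE.match(naan):
        raise ValidationError(
            f"NAAN must be exactly 5 decimal digits, got {naan!r}"
        )
    blade = "".join(rng.choice(BETANUMERIC) for _ in range(blade_length))
    return PID(naan=naan, shoulder=shoulder, blade=blade)


def parse_pid(text: str) -> PID:
    """Parse an ARK string into a :class:`PID`.

    Accepts both ``ark:naan/name`` and the legacy ``ark:/naan/name``
    spelling.  The name is split into shoulder and blade using the
    first-digit convention; a name containing no digit is treated as all
    blade.
    """
    if not isinstance(text, str):
        raise PIDParseError(f"expected a string, got {type(text).__name__}")
    stripped = text.strip()
    scheme, _, _ = stripped.partition(":")
    if scheme != "ark":
        raise PIDParseError(f"unsupported scheme {scheme!r} in {text!r}")
    m = _ARK_RE.match(stripped)
    if not m:
        raise PIDParseError(f"missing NAAN or name in ARK {text!r}")
    naan, name = m.group("naan"), m.group("name")
    if not _NAAN_RE.match(naan):
        raise PIDParseError(f"invalid NAAN {naan!r}: must be 5 decimal digits")
    sm = _SHOULDER_RE.match(name)
    if sm:
        return PID(naan=naan, shoulder=sm.group("shoulder"), blade=sm.group("blade"))
    return PID(naan=naan, shoulder="", blade=name)


def as_pid(value: "PID | str") -> PID:
    """Coerce a PID or ARK string to a :class:`PID`."""
    if isinstance(value, PID):
        return value
    return parse_pid(value)


def normalize(text: str) -> str:
    """Return the canonical slashless spelling of an ARK string."""
    return str(parse_pid(text))
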