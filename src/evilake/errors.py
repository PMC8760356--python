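"""Exception hierarchy shared by all evilake services."""


class EviLakeError(Exception):
    """Base class for every error raised by evilake."""


class PIDParseError(EviLakeError, ValueError):
    """A string could not be parsed as an ARK identifier."""


class ValidationError(EviLakeError, ValueError):
    """A record or request violates a structural constraint.

    Carries the full list of violations so callers can report them all.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class CycleError(ValidationError):
    """A write would make the provenance edge relation cyclic."""

    def __init__(self, cycle_path):
        self.cycle_path = list(cycle_path)
        pretty = " -> ".join(str(p) for p in self.cycle_path)
        super().__init__([f"provenance cycle: {pretty}"])


class NotFoundError(EviLakeError, KeyError):
    """A PID, job, or stored object does not exist."""

    def __str__(self):  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class ConflictError(EviLakeError):
    """A write targets a key or location that is already occupied."""


class IntegrityError(EviLakeError):
    """A cryptographic digest check failed."""


class CorruptionError(IntegrityError):
    """Stored bytes no longer match the digest recorded at write time."""


class ConfigurationError(EviLakeError):
    """An unknown or unavailable engine/option was requested."""


class StateError(EviLakeError):
    """An operation is not legal in the object's current state."""
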