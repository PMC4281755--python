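"""Exception hierarchy.

The CLI maps these onto exit codes: data problems (unreadable, malformed or
empty inputs, structural mismatches) exit 1, configuration problems exit 2.
"""


class IonfluxError(Exception):
    """Base class for all ionflux errors."""


class ParseError(IonfluxError):
    """A file exists but a record in it cannot be parsed."""


class StructureError(IonfluxError):
    """Inputs are individually valid but structurally inconsistent
    (e.g. frame atom count does not match the topology)."""


class EmptyInputError(IonfluxError):
    """An operation that needs at least one frame/value received none."""


class ConfigError(IonfluxError):
    """A configuration value is missing, malformed or self-contradictory."""


class InconsistencyError(IonfluxError):
    """Derived quantities contradict each other (e.g. transitions recorded
    out of a state with zero total dwell)."""
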