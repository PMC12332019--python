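"""Exception hierarchy for qubofs."""


class QubofsError(Exception):
    """Base class for all qubofs errors."""


class FormatError(QubofsError):
    """An input archive or serialized object does not match the expected layout."""


class DimensionError(QubofsError):
    """An array has an incompatible or non-divisible shape."""


class SpecError(QubofsError):
    """A specification object (synthetic spec, selection spec, config) is invalid."""


class CapacityError(QubofsError):
    """A problem exceeds a solver's size cap."""


class TuningError(QubofsError):
    """Penalty-weight tuning failed to reach the target cardinality."""


class ConfigError(QubofsError):
    """An experiment or model configuration is inconsistent."""
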