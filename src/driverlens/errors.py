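"""Exception hierarchy shared by all pipeline stages."""


class DriverlensError(Exception):
    """Base class for all errors raised by driverlens."""


class FormatError(DriverlensError):
    """Malformed input file: duplicate identifiers, non-numeric cells, bad shape."""


class ConsistencyError(DriverlensError):
    """Inputs are individually valid but mutually inconsistent."""


class VocabularyError(DriverlensError):
    """A token falls outside its controlled vocabulary."""


class ParameterError(DriverlensError):
    """An argument violates a precondition."""


class InsufficientReplicationError(ParameterError):
    """A group has too few samples for the requested test."""


class DegenerateSampleError(DriverlensError):
    """A sample cannot be normalized (e.g. all-zero counts)."""
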