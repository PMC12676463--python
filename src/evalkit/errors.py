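"""Exception hierarchy shared across the toolkit."""


class EvalkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(EvalkitError):
    """Malformed input text (GFA, VCF, hit table, ...)."""


class IntegrityError(EvalkitError):
    """Structurally valid input that violates referential integrity."""


class ParameterError(EvalkitError):
    """Invalid argument value."""


class CapacityError(EvalkitError):
    """A simulation request does not fit in the genome provided."""


class PlacementError(EvalkitError):
    """A region cannot be placed anywhere in the genome layout."""
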