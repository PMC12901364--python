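"""Exception hierarchy shared across the pipeline."""


class CareflowError(Exception):
    """Base class for all careflow errors."""


class SpecificationError(CareflowError):
    """A simulation or model specification violates its invariants."""


class FormatError(CareflowError):
    """An input file does not conform to its declared format."""


class ConfigurationError(CareflowError):
    """A configuration value (rule id, column map, rubric, quorum) is invalid."""


class DegenerateInputError(CareflowError):
    """An operation received an empty or otherwise degenerate input."""


class OrchestrationError(CareflowError):
    """No interpreter backend produced a structurally valid report."""
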