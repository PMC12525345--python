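"""Exception types shared across the pipeline stages."""


class DegnetError(Exception):
    """Base class for pipeline errors."""


class FormatError(DegnetError):
    """An input file does not have the expected columns/layout."""


class EmptyInputError(DegnetError):
    """An input file or table is empty where content is required."""


class EmptyNetworkError(DegnetError):
    """A filtering step removed every node from the network."""


class DegenerateNodeError(DegnetError):
    """A node violates a precondition (zero degree, zero-norm vector...)."""


class ValidationError(DegnetError):
    """A configuration object failed validation."""
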