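"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI exit code 2); everything else
surfacing from the library is an internal error (exit code 1).
"""


class IndikitError(Exception):
    """Base class for all package errors."""


class ValidationError(IndikitError):
    """Invalid input data, configuration, or arguments."""
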