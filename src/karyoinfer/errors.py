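"""Exception hierarchy.

Validation errors signal malformed or inconsistent *input*; computation
errors signal a request the data cannot support (e.g. an SD-based test with
N < 2).  The CLI maps them to distinct exit codes.
"""


class KaryoinferError(Exception):
    """Base class for all package errors."""


class ValidationError(KaryoinferError):
    """Input violates a documented precondition or file-format contract."""


class ComputationError(KaryoinferError):
    """Input is well-formed but the requested computation is undefined on it."""
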