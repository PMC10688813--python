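"""Exception hierarchy.

``ValidationError`` marks problems in user-supplied inputs (malformed
files, inconsistent labels, out-of-range parameters); the CLI maps it to
exit code 2. Everything else surfaces as a runtime failure (exit code 1).
"""


class MockqcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MockqcError, ValueError):
    """Invalid input data or configuration supplied by the caller."""
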