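"""Exception hierarchy.

``UmivarError`` marks conditions caused by user input (bad files, invalid
specs, out-of-range parameters); anything else escaping the package is an
internal error. The CLI maps the former to exit code 1 and the latter to 2.
"""


class UmivarError(Exception):
    """Base class for user-facing errors."""


class ParseError(UmivarError):
    """A file could not be parsed; the message names the offending line."""


class SpecError(UmivarError):
    """A simulation or run specification violates its schema."""
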