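"""Exception hierarchy.

Every user-facing failure (malformed input file, violated precondition,
degenerate data) raises :class:`CoexnetError`; the CLI maps it to exit code 1.
Programming errors keep their builtin types.
"""


class CoexnetError(Exception):
    """Base class for validation and input errors."""


class LoadError(CoexnetError):
    """A file could not be parsed or violated a format invariant."""
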