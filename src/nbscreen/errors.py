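"""Exception hierarchy shared across the toolkit.

Every reader and rule engine in this package rejects bad input instead of
coercing it; these classes let callers (and the CLI) distinguish the three
failure families: bad configuration, malformed input files, and inputs that
are syntactically fine but scientifically degenerate.
"""


class NbscreenError(Exception):
    """Base class for all errors raised by nbscreen."""


class ConfigurationError(NbscreenError):
    """A cutoff profile, threshold set or rule version is missing or invalid."""


class SchemaError(NbscreenError):
    """An input file violates its declared schema (missing columns,
    missing annotations, mismatched amplicon sets, ...)."""


class ParseError(NbscreenError):
    """A field in an input file could not be parsed; carries file/line context
    in the message whenever available."""


class DegenerateInputError(NbscreenError):
    """Input is well-formed but unusable (e.g. all-zero coverage)."""
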