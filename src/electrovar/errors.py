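"""Exception hierarchy.

All user-facing failures derive from :class:`ElectrovarError` so the CLI can
map them to a "user error" exit status; anything else is an internal error.
"""


class ElectrovarError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ElectrovarError):
    """Invalid simulation or pipeline configuration."""


class ParseError(ElectrovarError):
    """A text input file could not be parsed."""


class IntegrityError(ElectrovarError):
    """Parsed data violates a structural invariant (e.g. duplicate labels)."""


class ValidationError(ElectrovarError):
    """A numeric object violates its invariants (e.g. a singular affine)."""


class PipelineError(ElectrovarError):
    """A pipeline stage failed; the message names the stage."""
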