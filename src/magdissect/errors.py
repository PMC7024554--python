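"""Exception hierarchy shared across the package."""


class MagdissectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MagdissectError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(MagdissectError):
    """A value violates a documented domain constraint."""


class IntegrityError(MagdissectError):
    """Cross-referential breakage between input tables (names the offender)."""
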