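"""Exception hierarchy shared across the package."""


class ClaimForgeError(Exception):
    """Base class for all package errors."""


class BundleLoadError(ClaimForgeError):
    """A reference table is missing, empty, or unreadable."""


class BundleIntegrityError(ClaimForgeError):
    """A loaded reference table violates its invariants (duplicate NPI, bad code shape, ...)."""


class ConfigError(ClaimForgeError):
    """A generator configuration value is out of its allowed range."""


class SerializationError(ClaimForgeError):
    """A claim cannot be serialized (invalid claim, empty batch, ...)."""


class X12ParseError(ClaimForgeError):
    """X12 text could not be parsed; carries the 1-based segment index when known."""

    def __init__(self, message: str, segment_index: int = 0):
        super().__init__(message)
        self.segment_index = segment_index
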