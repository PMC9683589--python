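"""Exception hierarchy for phaseslope."""


class PhaseslopeError(Exception):
    """Base class for all package-specific errors."""


class DamFormatError(PhaseslopeError):
    """Raised when a DAM2 monitor file violates the supported dialect."""


class ProtocolError(PhaseslopeError):
    """Raised for inconsistent environmental schedules or out-of-span queries."""


class LandmarkError(PhaseslopeError):
    """Raised when slope landmarks cannot be determined from a median profile."""


class ConfigError(PhaseslopeError):
    """Raised for invalid run configurations."""
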