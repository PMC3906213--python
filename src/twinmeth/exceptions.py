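"""Exception hierarchy. Everything raised on purpose derives from TwinMethError."""


class TwinMethError(Exception):
    """Base class for all package errors."""


class ConfigError(TwinMethError):
    """Invalid simulation or run configuration."""


class ValidationError(TwinMethError):
    """A data file or in-memory table violates its contract."""


class PairingError(ValidationError):
    """Sample-sheet twin pairing is inconsistent."""


class DesignError(TwinMethError):
    """An analysis design cannot be formed from the given samples."""
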