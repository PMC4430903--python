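"""Exception types shared across the package."""


class RareScanError(Exception):
    """Base class for all rarescan errors."""


class ConfigurationError(RareScanError, ValueError):
    """Invalid simulator or pipeline configuration (e.g. overlap >= tile extent)."""


class FormatError(RareScanError, ValueError):
    """Malformed or inconsistent on-disk artifact (tileset, detection table, ...)."""


class CalibrationError(RareScanError, RuntimeError):
    """Channel registration could not be estimated (e.g. structureless image)."""
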