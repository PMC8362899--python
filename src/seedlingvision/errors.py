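"""Exception hierarchy for seedlingvision."""


class SeedlingVisionError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SeedlingVisionError, ValueError):
    """A data argument violates a documented precondition."""


class ConfigError(SeedlingVisionError, ValueError):
    """A configuration value or file is invalid."""


class GeometryError(SeedlingVisionError, ValueError):
    """A tray layout or cell index is inconsistent with the image."""
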