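"""Exception hierarchy."""


class CraniomorphError(Exception):
    """Base class for all package errors."""


class CloudSchemaError(CraniomorphError):
    """A cloud (in memory or on disk) violates the marker schema."""


class MissingMarkerError(CraniomorphError):
    """An operation required a marker that is flagged absent."""


class FrameError(CraniomorphError):
    """The reference frame cannot be established."""


class DegenerateFrameError(FrameError):
    """Reference stickers are collinear or coincident."""


class ConfigError(CraniomorphError):
    """Invalid run configuration."""
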