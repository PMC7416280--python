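"""Exception hierarchy for voxencode."""


class VoxencodeError(Exception):
    """Base class for all voxencode errors."""


class ConfigurationError(VoxencodeError, ValueError):
    """A configuration object or parameter is invalid."""


class DataShapeError(VoxencodeError, ValueError):
    """Array shapes or index sets are inconsistent."""


class InputDataError(VoxencodeError, ValueError):
    """An input file or in-memory input is malformed."""
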