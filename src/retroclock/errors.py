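"""Exception hierarchy.

``RetroclockError`` is the common base; ``InputError`` marks problems the
caller can fix (bad arguments, malformed files), distinct from numerical
conditions such as distance saturation that arise from the data itself.
"""


class RetroclockError(Exception):
    """Base class for all package errors."""


class InputError(RetroclockError, ValueError):
    """Invalid argument or precondition violation."""


class FormatError(InputError):
    """Malformed input file; message names the offending line/record."""


class PlacementError(RetroclockError):
    """Could not place an element without overlap within the retry budget."""


class UndefinedDistanceError(RetroclockError):
    """No usable sites remain after masking/gap removal."""


class SaturationError(RetroclockError):
    """Observed divergence too high for the K2P correction to be defined."""


class StageError(RetroclockError):
    """A pipeline stage failed; message names the stage."""
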