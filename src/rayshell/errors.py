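"""Exception hierarchy for rayshell."""


class RayshellError(Exception):
    """Base class for all rayshell errors."""


class BoundaryError(RayshellError):
    """Invalid closed boundary (self-intersecting, degenerate, too few points)."""


class ParameterError(RayshellError):
    """Invalid solver or operation parameter."""


class SamplingError(RayshellError):
    """Ray sampling left the image domain."""


class NumericalError(RayshellError):
    """Non-finite value encountered during iteration."""


class FormatError(RayshellError):
    """Malformed or inconsistent input file."""


class ScoreError(RayshellError):
    """Overlap scores undefined (zero-area region)."""


class SpecError(RayshellError):
    """Invalid phantom specification."""
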