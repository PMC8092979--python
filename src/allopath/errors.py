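"""Exception hierarchy shared across the pipeline stages."""


class AllopathError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AllopathError):
    """An input table does not conform to the expected dialect."""


class DuplicateRecordError(FormatError):
    """The same (residue, snapshot) cell appears more than once."""


class ValidationError(AllopathError):
    """Well-formed input that violates a semantic invariant."""


class GeometryError(AllopathError):
    """A structural operation received degenerate coordinates."""


class ZeroVarianceError(AllopathError):
    """A correlation is undefined because one input series is constant.

    Raised instead of returning a sentinel value so that undefined
    coefficients can never be mistaken for a numeric zero.
    """


class PipelineError(AllopathError):
    """A pipeline stage failed; the message names the stage."""
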