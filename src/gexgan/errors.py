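"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`GexganError`
so callers (and the CLI) can distinguish usage errors from bugs.
"""


class GexganError(Exception):
    """Base class for all gexgan errors."""


class FormatError(GexganError):
    """Malformed input file (duplicate ids, bad header, ...)."""


class ParseError(FormatError):
    """Non-numeric cell or unparseable content; message carries coordinates."""


class LabelingError(GexganError):
    """Sample present in the matrix but missing from the label table."""


class AlignmentError(GexganError):
    """Gene sets / shapes of two objects do not line up."""


class DomainError(GexganError):
    """Values outside the mathematical domain of an operation."""


class DegenerateDataError(GexganError):
    """Input is valid but degenerate (zero variance, empty intersection...)."""


class ParameterError(GexganError):
    """Invalid parameter value for an operation."""


class StratificationError(GexganError):
    """A (tissue, condition) stratum is too small to split."""


class CodecError(GexganError):
    """A label unknown to the fitted label codec."""


class DivergenceError(GexganError):
    """Non-finite loss encountered during adversarial training."""
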