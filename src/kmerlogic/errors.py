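"""Exception types shared across the package."""


class KmerlogicError(Exception):
    """Base class for package errors."""


class ValidationError(KmerlogicError, ValueError):
    """Input violates a documented invariant (duplicate ids, empty dataset, ...)."""


class ParameterError(KmerlogicError, ValueError):
    """A parameter is outside its documented range."""


class FastaFormatError(KmerlogicError, ValueError):
    """The input file is not valid FASTA; the message names the offending line."""


class UndefinedMetricError(KmerlogicError, ZeroDivisionError):
    """A metric is undefined for the given counts (e.g. accuracy with t = 0)."""
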