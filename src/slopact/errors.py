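"""Exception hierarchy shared across the pipeline stages."""


class SlopactError(Exception):
    """Base class for all package errors."""


class ParameterError(SlopactError, ValueError):
    """An argument or configuration field is outside its admissible range."""


class RecordRejectionError(SlopactError):
    """A record cannot be represented in an experiment (too many missing
    samples, or no activity epoch of the required length).

    Rejections are recoverable at the cohort level: the pipeline collects
    them and reports the record as unrepresented rather than aborting.
    """

    def __init__(self, message: str, *, source_id: str | None = None,
                 fraction: float | None = None):
        super().__init__(message)
        self.source_id = source_id
        self.fraction = fraction


class DegenerateInputError(SlopactError, ValueError):
    """The input is formally valid but the operation is undefined on it
    (e.g. z-scoring a constant series, normalising an all-zero collection)."""


class UndefinedEntropyError(SlopactError, ArithmeticError):
    """The entropy estimate does not exist for this series (e.g. sample
    entropy with zero template matches)."""


class ClassEmptyError(SlopactError):
    """A mood-state class ended up with no usable samples."""
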