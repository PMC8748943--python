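"""Exception hierarchy for cardiomotor."""


class CardiomotorError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CardiomotorError, ValueError):
    """A parameter violates a documented precondition."""


class EmptyTrainError(CardiomotorError):
    """No R-peaks could be detected / an empty peak train was supplied."""


class QCError(CardiomotorError):
    """A quality-control check failed hard (e.g. physiologically impossible rate)."""


class DegenerateDataError(CardiomotorError):
    """The data admit no valid statistic (zero variance, too few points, ...)."""


class SchemaError(CardiomotorError):
    """An input table violates the expected schema; message names file/row/column."""
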