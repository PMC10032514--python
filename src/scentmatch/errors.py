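"""Exception hierarchy shared by all scentmatch stages."""


class ScentMatchError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ScentMatchError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class RowError(FormatError):
    """A single row of an input file is invalid; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ValidationError(ScentMatchError):
    """An in-memory object violates one of its invariants."""


class AlignmentError(ScentMatchError):
    """A sample cannot be aligned (e.g. too few ladder markers found)."""


class EmptyModelError(ScentMatchError):
    """Ratio selection produced an empty model; lower T2 or the grids."""


class SingularCovarianceError(ScentMatchError):
    """Covariance matrix is singular; reduce the data to PCA scores first."""


class UndefinedSimilarityError(ScentMatchError):
    """A similarity score is undefined (constant or zero vector)."""
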