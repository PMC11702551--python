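"""Exception hierarchy shared across rxbench."""


class RxbenchError(Exception):
    """Base class for all rxbench errors."""


class InvalidInputError(RxbenchError, ValueError):
    """An argument violates a documented precondition.

    Covers malformed vectors/fingerprints, bad parameters (cutoffs, ranks,
    metrics), missing percentile context, non-bijective match tables, and
    withholding a drug that is not associated.
    """


class InsufficientDataError(RxbenchError, ValueError):
    """Not enough data to perform the requested operation.

    Covers libraries with fewer than two compounds, indications with fewer
    than two drugs, empty seed sets, empty site sets, unsplittable mappings,
    and correlation inputs that are too small or constant.
    """


class FormatError(RxbenchError, ValueError):
    """A file does not conform to the expected tabular format."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)
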