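"""Exception hierarchy shared by all evaluation modules."""


class MetaevalError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MetaevalError):
    """A file does not follow the expected dialect (missing header, wrong columns)."""


class ParseError(FormatError):
    """A single line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class StructuralError(MetaevalError):
    """The taxonomy graph violates a structural invariant (missing parent, cycle)."""


class UnknownTaxonError(MetaevalError):
    """A taxon ID is absent from both the nodes and the merged tables."""

    def __init__(self, taxid: int):
        self.taxid = taxid
        super().__init__(f"unknown taxon ID {taxid}")


class UndefinedMetricError(MetaevalError):
    """The metric is mathematically undefined on this input (e.g. empty bin set)."""


class EmptyEvaluationError(MetaevalError):
    """Prediction and gold standard share no sequences; nothing can be scored."""
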