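"""Exception hierarchy shared across the toolkit."""


class TopicScreenError(Exception):
    """Base class for all topicscreen errors."""


class SchemaError(TopicScreenError):
    """An input file is readable but does not match the expected schema."""


class ValidationError(TopicScreenError):
    """An in-memory object or argument violates a documented precondition."""


class ParseError(TopicScreenError):
    """A serialised file contains a malformed record.

    Attributes
    ----------
    line_number : int or None
        1-based number of the offending line, when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedMetricError(TopicScreenError):
    """A metric is mathematically undefined for the given inputs
    (e.g. ROC-AUC when only one class is present)."""
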