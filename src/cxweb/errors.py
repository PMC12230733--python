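"""Exception hierarchy shared across the toolkit."""


class CxWebError(Exception):
    """Base class for all toolkit errors."""


class ConflictError(CxWebError):
    """An id or name is already in use."""


class ElementReferenceError(CxWebError):
    """An operation referenced an element that does not exist."""


class TypeCoercionError(CxWebError):
    """A value could not be coerced to its declared datatype."""


class CxParseError(CxWebError):
    """Input text could not be parsed.

    ``position`` carries the character offset when known.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class CxValidationError(CxWebError):
    """A document violated a structural rule of the dialect."""


class ContractError(CxWebError):
    """A precondition of an operation was violated."""


class TransportError(CxWebError):
    """An HTTP-like transport returned a non-success status."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class TaskFailedError(CxWebError):
    """A remote task reached the failed state; carries the server message."""


class TaskTimeoutError(CxWebError):
    """Polling a remote task exceeded the retry budget."""


class RowImportError(CxWebError):
    """A tabular row could not be imported; carries the 1-based row number."""

    def __init__(self, message: str, row: int):
        super().__init__(message)
        self.row = row
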