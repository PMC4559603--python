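"""Exception hierarchy.

Every error raised by the package derives from :class:`TabbenchError`, so
callers (the CLI in particular) can catch one type. Subclasses are grouped by
the contract they enforce rather than by module.
"""


class TabbenchError(Exception):
    """Base class for all package errors."""


class ManifestError(TabbenchError):
    """Malformed or invalid app manifest (bad JSON, unknown type token...)."""


class ValidationError(TabbenchError):
    """A parameter value does not conform to its declared type or bounds."""


class SchemaError(TabbenchError):
    """A column reference does not resolve against the table schema."""


class StructureError(TabbenchError):
    """A script's block/directive structure is malformed."""


class BackendError(TabbenchError):
    """The execution backend failed to evaluate a unit or resolve a name.

    ``output`` carries the backend's verbatim error text, which execution
    keeps in the transcript (console-pane behavior).
    """

    def __init__(self, message: str, output: str | None = None):
        super().__init__(message)
        self.output = output


class OutputError(TabbenchError):
    """A declared app output could not be collected from the backend."""


class ShapeError(TabbenchError):
    """A payload's dimensions disagree with the receiving table."""


class WorkflowError(TabbenchError):
    """A workflow step could not run (e.g. its input table is missing)."""

    def __init__(self, message: str, step_index: int | None = None):
        super().__init__(message)
        self.step_index = step_index


class FormulaError(TabbenchError):
    """Formula text failed to parse; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class FormatError(TabbenchError):
    """A data file (WIG, BED, CSV) violates its format."""


class RecordError(FormatError):
    """A single record in a data file is invalid; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.line_number = line_number


class DomainError(TabbenchError):
    """A numeric argument lies outside the mathematical domain."""


class ArityError(TabbenchError):
    """A set collection has an unsupported number of member sets."""


class DegenerateShapeError(TabbenchError):
    """A 2-D filter shape has zero area."""


class EmptyDomainError(TabbenchError):
    """An operation over values found nothing to operate on (all missing)."""
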