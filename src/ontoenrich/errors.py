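"""Exception hierarchy.

User-facing errors (bad input files, bad flags) derive from
:class:`UserInputError` so the CLI can map them to exit code 1;
anything else is an internal error (exit code 2).
"""


class OntoEnrichError(Exception):
    """Base class for all package errors."""


class UserInputError(OntoEnrichError):
    """Errors attributable to user-supplied input or configuration."""


class OboParseError(UserInputError):
    """Malformed OBO input; message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class GafParseError(UserInputError):
    """Malformed GAF input; message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class OntologyValidationError(UserInputError):
    """Ontology violates a structural invariant (e.g. a cycle)."""


class ConfigurationError(UserInputError):
    """Mutually exclusive or otherwise invalid options."""


class AnnotationError(UserInputError):
    """No usable annotations survive filtering/resolution."""


class QueryError(UserInputError):
    """A query set is empty after identifier resolution."""


class StatsDomainError(OntoEnrichError):
    """Count arguments violate the hypergeometric preconditions."""


class GraphViewError(OntoEnrichError):
    """A display-graph request references unknown terms."""


class ReportError(OntoEnrichError):
    """Report serialization failed a consistency precondition."""


class FixtureError(OntoEnrichError):
    """A synthetic-fixture specification is unsatisfiable."""
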