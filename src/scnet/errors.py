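"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`ValidationError` and its
subclasses (bad input data or configuration) map to exit code 1;
:class:`ComputationError` subclasses (statistical or numerical
degeneracy discovered at run time) map to exit code 2.
"""


class ScnetError(Exception):
    """Base class for all package errors."""


class ValidationError(ScnetError):
    """Invalid input data, schema, or configuration."""


class ParseError(ValidationError):
    """A file could not be parsed at all (empty, malformed)."""


class SchemaError(ValidationError):
    """A table is parseable but misses or duplicates required columns."""


class UnknownStructureError(ValidationError):
    """Structure or hemisphere name not in the atlas."""


class ConfigError(ValidationError):
    """Invalid pipeline configuration key or value."""


class ComputationError(ScnetError):
    """Statistical or numerical degeneracy at run time."""


class InsufficientSampleError(ComputationError):
    """Too few subjects for the requested estimate."""


class DegenerateColumnError(ComputationError):
    """A region has zero residual variance; correlation undefined."""

    def __init__(self, region: str):
        self.region = region
        super().__init__(f"zero residual variance in region {region!r}")


class UndefinedMeasureError(ComputationError):
    """A graph measure is undefined on this input (e.g. singleton graph)."""


class RewiringError(ComputationError):
    """Degree-preserving rewiring impossible (too few edges)."""


class NullDegenerateError(ComputationError):
    """The random-reference ensemble yielded a degenerate normalizer."""


class DegenerateTableError(ComputationError):
    """A contingency table has a zero marginal."""


class TemplateInvalidError(ValidationError):
    """A correlation template parameterization is not positive definite."""
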