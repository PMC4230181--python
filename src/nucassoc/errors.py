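"""Exception hierarchy shared across the package."""


class NucAssocError(Exception):
    """Base class for all nucassoc-specific errors."""


class ConfigError(NucAssocError):
    """Invalid geometry or run configuration."""


class InvalidRelationError(NucAssocError):
    """Relation is not one of trans / cis / homologous."""


class EmptySimulationError(NucAssocError):
    """A Monte-Carlo estimate was requested with zero trials."""


class CalibrationError(NucAssocError):
    """Bisection could not reach the requested null frequency."""


class MissingReferenceError(NucAssocError):
    """No published random-expectation constant for this ploidy/relation."""


class SchemaError(NucAssocError):
    """A scored-nuclei table violates the TSV schema."""


class UnscorableError(NucAssocError):
    """Neither flags nor positions allow the requested metric to be scored."""


class AmbiguousPloidyError(NucAssocError):
    """Mixed ploidy classes given to a metric that needs a single class."""


class CohesionUndefinedError(NucAssocError):
    """Cohesion scoring requested for unreplicated (2C) nuclei."""


class AnnotationError(NucAssocError):
    """Probe annotation does not support the requested operation."""


class FormatError(NucAssocError):
    """Malformed input file (carries a line number where possible)."""


class UndefinedCorrelationError(NucAssocError):
    """Rank correlation undefined (constant input sequence)."""
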