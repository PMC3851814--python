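"""Exception hierarchy for ppipred."""


class PpipredError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(PpipredError):
    """Raised when an OBO file cannot be parsed."""


class OntologyValidationError(PpipredError):
    """Raised when a parsed ontology violates structural invariants (cycles,
    cross-aspect edges, multiple aspect roots)."""


class GafParseError(PpipredError):
    """Raised when a GAF annotation file cannot be read."""


class EmptyAnnotationError(PpipredError):
    """Raised when an annotation source yields zero usable rows."""


class EmptyCorpusError(PpipredError):
    """Raised when an IC computation is attempted on an aspect with no
    annotated proteins."""


class DifferentAspectsError(PpipredError):
    """Raised when two terms from different GO aspects are compared."""


class UnknownTermError(PpipredError):
    """Raised when a term id is not present in the ontology."""


class UnknownProteinError(PpipredError):
    """Raised when a protein id is not a node of the PPI network."""


class MalformedTableError(PpipredError):
    """Raised for malformed lines in TSV inputs; carries the line number."""


class FeatureConfigError(PpipredError):
    """Raised for unrecognized feature names in a feature configuration."""


class SingleClassError(PpipredError):
    """Raised when training or ROC analysis receives only one class."""
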