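"""Exception hierarchy shared across the pipeline stages."""


class NanoconcordError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NanoconcordError):
    """A configuration or input value violates a documented precondition."""


class FormatError(NanoconcordError):
    """A file could be opened but its contents violate the expected format."""


class AlignmentError(NanoconcordError):
    """Sample identifiers disagree between a count matrix and its annotations."""


class SingularDesignError(NanoconcordError):
    """A design matrix (regression or batch model) is rank deficient."""


class ProvenanceError(NanoconcordError):
    """A processing stage was applied twice, or out of order."""


class LibraryMismatchError(NanoconcordError):
    """Two enrichment results were computed against different term libraries."""
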