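"""Exception hierarchy for cogassoc."""


class CogassocError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CogassocError):
    """Invalid cohort / pipeline configuration."""


class GenerationError(CogassocError):
    """Synthetic-data generation cannot proceed (e.g. missing genotype)."""


class MalformedSessionError(CogassocError):
    """A CPT session violates the 480-trial task structure."""


class DomainError(CogassocError, ValueError):
    """Numeric input outside the mathematical domain of an index."""


class DegenerateDesignError(CogassocError):
    """A model factor has fewer than two observed levels, or the data
    cannot support the requested test (constant column, zero margin...)."""


class AliasingError(DegenerateDesignError):
    """Rank-deficient design; carries the name of the aliased term."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"design is rank deficient: term {term!r} is aliased")


class BoundedSearchError(CogassocError):
    """A monotone search hit its configured ceiling before succeeding."""

    def __init__(self, bound: int, message: str = ""):
        self.bound = bound
        super().__init__(message or f"search exceeded configured ceiling {bound}")
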