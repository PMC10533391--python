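"""Exception hierarchy shared across the package."""


class InvadivError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(InvadivError, ValueError):
    """A caller supplied an argument outside the documented domain."""


class SchemaError(InvadivError):
    """An input table is missing required columns or holds malformed rows."""


class IOFailure(InvadivError):
    """A file could not be read or written."""


class CoverageError(InvadivError):
    """A lookup table does not cover a region/plot that the data references."""


class MissingTaxonError(InvadivError):
    """A community references tips absent from the tree."""

    def __init__(self, taxa):
        self.taxa = sorted(taxa)
        super().__init__(f"taxa not found in tree: {', '.join(self.taxa)}")


class UndefinedStatisticError(InvadivError):
    """A statistic is undefined for this input (zero variance, single class...)."""


class ConvergenceError(InvadivError):
    """A model fit failed to converge."""


class GenerationFailure(InvadivError):
    """The synthetic generator could not satisfy its invariants."""


class MissingArtifactError(InvadivError):
    """A pipeline stage output required by a later stage is absent or unreadable."""
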