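"""Exception hierarchy for the predation pan-GWAS pipeline."""


class PredGwasError(Exception):
    """Base class for all pipeline errors."""


class MalformedFileError(PredGwasError):
    """An input file does not follow the expected dialect."""


class DuplicateIdentifierError(PredGwasError):
    """A strain or cluster identifier occurs more than once."""


class PhenotypeParseError(PredGwasError):
    """A phenotype cell is non-numeric or otherwise unparseable."""


class PhenotypeDomainError(PredGwasError):
    """A phenotype value is outside its domain (zone diameters are >= 0)."""


class InsufficientDataError(PredGwasError):
    """Too few non-missing observations for tertile binarization."""


class DegenerateDesignError(PredGwasError):
    """A 2x2 design with an empty margin, or no informative prey at all."""


class InsufficientAnnotationError(PredGwasError):
    """No functionally annotated hits available for a profile comparison."""


class ConfigError(PredGwasError):
    """An invalid simulation or pipeline configuration."""


class FitError(PredGwasError):
    """A curve fit cannot be performed (too few usable points)."""


class NoSolutionError(PredGwasError):
    """A prediction has no solution (non-decaying power law)."""
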