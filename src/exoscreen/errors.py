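"""Exception hierarchy shared across the pipeline stages."""


class ExoscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(ExoscreenError):
    """A sequence contains a character outside the accepted RNA/DNA alphabet."""


class CoordinateError(ExoscreenError):
    """A 1-based coordinate or window lies outside the sequence."""


class FormatError(ExoscreenError):
    """A structured input file (TSV, Vienna, PDB) violates its format contract."""


class GenerationError(ExoscreenError):
    """Constrained random generation exhausted its attempt budget."""


class MetricViolationError(ExoscreenError):
    """A user-supplied metric returned a negative or non-finite distance."""


class InsufficientAtomsError(ExoscreenError):
    """Fewer than 3 paired atoms: the optimal rotation is under-determined."""


class SpecError(ExoscreenError):
    """A synthetic-data specification is internally infeasible."""


class EmptyInputError(ExoscreenError):
    """An input container (PDB ensemble, item list) is empty."""
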