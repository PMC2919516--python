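"""Exception hierarchy shared across the package."""


class PentamodError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PentamodError, ValueError):
    """A parameter violates a documented precondition (e.g. k <= 0)."""


class CapacityError(PentamodError):
    """The requested k-mer space does not fit the dense-array guard (k > 6)."""


class InvalidResidueError(PentamodError, ValueError):
    """A peptide contains a letter outside the 20 standard residues."""


class FastaParseError(PentamodError):
    """A FASTA stream could not be parsed; names the offending record."""


class ScaleError(PentamodError, ValueError):
    """A residue scale is incomplete or a residue is missing from it."""


class DegenerateVarianceError(PentamodError):
    """Zero pooled within-group variance with unequal group means."""


class TranslationError(PentamodError, ValueError):
    """A codon cannot be translated (stop codon or ambiguous base)."""


class InvalidModelError(PentamodError, ValueError):
    """A codon model is missing required data (e.g. usage fractions)."""


class HitTableParseError(PentamodError):
    """A tabular alignment-report row is malformed; carries the line number."""


class AmbiguousAnnotationError(PentamodError):
    """A hit overlaps gene-level features on contradictory strands."""


class InfeasiblePlantError(PentamodError):
    """A synthetic-data plant cannot be realized within the given geometry."""
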