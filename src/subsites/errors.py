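"""Exception hierarchy for the subsites toolkit."""


class SubsitesError(Exception):
    """Base class for all package errors."""


class PDBParseError(SubsitesError):
    """Raised when a PDB document cannot be interpreted."""


class PDBFormatError(SubsitesError):
    """Raised when a structure cannot be serialized to PDB columns."""


class SuperpositionError(SubsitesError):
    """Raised for degenerate or under-determined superposition input."""


class AlignmentError(SubsitesError):
    """Raised on illegal sequence input."""


class AnnotationError(SubsitesError):
    """Raised when the annotation workflow cannot proceed."""


class NotAnnotatable(AnnotationError):
    """No homologue in the annotated library passes the identity floor."""


class UnreplaceableNnaa(SubsitesError):
    """No natural amino acid is chemically similar enough to the NNAA."""


class UnmodellableComplex(SubsitesError):
    """Peptide reconstruction cannot avoid steric clashes with the enzyme."""


class SamplingError(SubsitesError):
    """Raised when a Monte Carlo run diverges or input is invalid."""


class EnergyError(SubsitesError):
    """Raised for ill-defined energy evaluations (e.g. coincident atoms)."""
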