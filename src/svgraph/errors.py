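"""Typed exceptions raised across the package."""


class SVGraphError(Exception):
    """Base class for all package errors."""


class UnsupportedSVTypeError(SVGraphError):
    """The variant type cannot be represented as a local allele graph."""


class MissingAltSequenceError(SVGraphError):
    """An insertion/swap record lacks a resolved alternative sequence."""


class ReferenceFetchError(SVGraphError):
    """Reference sequence could not be fetched over the required span."""


class AlignmentInputError(SVGraphError):
    """Invalid input to the graph aligner (e.g. empty read)."""


class GenotypingError(SVGraphError):
    """Invalid input to the genotype likelihood model."""


class VcfFormatError(SVGraphError):
    """Malformed or unsupported VCF content."""


class BamAccessError(SVGraphError):
    """BAM/CRAM file or its index could not be used."""


class MatchError(SVGraphError):
    """Two SV records do not satisfy the required matching rule."""


class SimulationError(SVGraphError):
    """Simulation could not satisfy its constraints (e.g. SV placement)."""
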