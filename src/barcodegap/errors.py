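"""Exception hierarchy for the barcodegap package.

All errors raised by the library derive from :class:`BarcodeGapError`, so
callers (in particular the CLI) can distinguish pipeline failures from
programming errors.
"""


class BarcodeGapError(Exception):
    """Base class for all barcodegap errors."""


class FastaParseError(BarcodeGapError):
    """A FASTA file could not be parsed (empty file, duplicate ids, bad characters)."""


class AlignmentIntegrityError(BarcodeGapError):
    """An alignment violated an invariant (ragged lengths, all-gap sequence)."""


class MetadataError(BarcodeGapError):
    """A sample metadata table was malformed or inconsistent with an alignment."""


class UndefinedDistanceError(BarcodeGapError):
    """A pairwise distance is undefined because no sites could be compared."""


class SaturationError(BarcodeGapError):
    """Observed divergence exceeds the domain of the distance formula."""


class TreeError(BarcodeGapError):
    """Invalid input to tree construction or bootstrap."""


class PrimerError(BarcodeGapError):
    """Invalid primer/template input to the primer scanner."""


class SimulationError(BarcodeGapError):
    """Invalid simulation configuration."""


class ConfigError(BarcodeGapError):
    """Invalid pipeline configuration."""
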