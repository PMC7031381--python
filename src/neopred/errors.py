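"""Exception hierarchy shared across the package."""


class NeopredError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NeopredError):
    """Invalid configuration value or unknown option."""


class ParseError(NeopredError):
    """Malformed input record; the message names the offending line."""


class EmptyStructure(NeopredError):
    """Structure input contains no canonical residues."""


class DegenerateCounts(NeopredError):
    """Contact counts contain no information (zero total)."""


class AlleleError(NeopredError):
    """HLA allele name cannot be parsed."""


class AlphabetError(NeopredError):
    """Sequence contains characters outside the amino-acid alphabet."""


class ShapeError(NeopredError):
    """Tensor shapes are incompatible."""


class DegenerateLabels(NeopredError):
    """A label vector contains a single class."""


class ReferenceMismatch(NeopredError):
    """Protein sequence disagrees with a mutation's reference residue."""


class EmptyFeatureSet(NeopredError):
    """No feature survives the frequency filter."""


class InsufficientControl(NeopredError):
    """Not enough control features to match the functional matrix."""


class MarkerError(NeopredError):
    """No usable immune marker genes."""


class DegenerateDistribution(NeopredError):
    """A vector is constant where spread is required."""
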