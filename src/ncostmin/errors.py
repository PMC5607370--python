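"""Exception hierarchy shared across the package."""


class NcostminError(Exception):
    """Base class for all package errors."""


class FastaFormatError(NcostminError):
    """Malformed or empty FASTA input."""


class AlphabetError(NcostminError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(NcostminError):
    """Feature coordinates inconsistent with themselves or the genome."""


class FrameError(NcostminError):
    """Coding span length not divisible by three."""


class TranslationError(NcostminError):
    """Premature stop codon or missing terminal stop."""


class ConfigurationError(NcostminError):
    """Invalid parameter, pattern, or simulation configuration."""
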