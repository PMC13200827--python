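"""Exception hierarchy shared across the pipeline stages."""


class GradescapeError(Exception):
    """Base class for all package-specific errors."""


class AlleleError(GradescapeError, ValueError):
    """A base that is not one of A/C/G/T, or ref == alt."""


class ContextError(GradescapeError, ValueError):
    """Trinucleotide context inconsistent with the variant's ref allele."""


class CoordinateError(GradescapeError, ValueError):
    """A locus falls outside the supplied genome."""


class ContextUnavailableError(GradescapeError, ValueError):
    """A required trinucleotide context does not occur in the genome."""


class SizingError(GradescapeError, ValueError):
    """Requested synthetic geometry cannot fit on the chromosomes."""


class DecompositionError(GradescapeError, ValueError):
    """Signature decomposition requested on an unusable spectrum."""


class ConfigError(GradescapeError, ValueError):
    """A pipeline configuration is missing or inconsistent."""
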