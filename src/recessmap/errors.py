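"""Exception hierarchy shared by all recessmap modules."""


class RecessmapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RecessmapError):
    """A file did not conform to its expected dialect (PED/MAP, VCF, BED, FASTA)."""


class DomainError(RecessmapError, ValueError):
    """An operation received values outside its mathematical/biological domain."""


class ConfigurationError(RecessmapError):
    """Inputs are individually valid but mutually inconsistent for the requested run."""


class UndefinedLDError(DomainError):
    """Linkage disequilibrium is undefined (a locus is monomorphic among complete pairs)."""
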