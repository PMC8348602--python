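"""Exception hierarchy shared across the pipeline."""


class MafdivergeError(Exception):
    """Base class for all package errors."""


class FormatError(MafdivergeError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class ValidationError(MafdivergeError):
    """A record violates a domain invariant (e.g. MAF > 0.5, p outside (0,1])."""


class UndefinedFrequencyError(MafdivergeError):
    """Allele frequency requested for a variant with no non-missing genotypes."""


class PipelineError(MafdivergeError):
    """Configuration or orchestration failure in the end-to-end pipeline."""
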