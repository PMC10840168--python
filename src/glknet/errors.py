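"""Exception hierarchy for glknet."""


class GlknetError(Exception):
    """Base class for all glknet errors."""


class ConfigurationError(GlknetError):
    """An invalid configuration value; the message names the offending field."""


class DataIntegrityError(GlknetError):
    """Input data contradicts itself (e.g. VCF ref allele vs genome sequence)."""


class InfeasibleEdgeSetError(GlknetError):
    """A requested set of partial correlations admits no positive-definite precision matrix."""


class PipelineError(GlknetError):
    """A pipeline stage failed; the message names the stage and offending record."""
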