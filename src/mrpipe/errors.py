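"""Exception hierarchy for the MR pipeline."""


class MRPipeError(Exception):
    """Base class for all package errors."""


class FormatError(MRPipeError):
    """A file does not conform to the expected layout (missing column, non-square matrix...)."""


class ValidationError(MRPipeError):
    """A value violates a domain invariant (SE <= 0, allele not in {A,C,G,T}...)."""


class EstimatorError(MRPipeError):
    """An estimator cannot run on the instruments it was given."""


class PipelineError(MRPipeError):
    """A whole-analysis failure, e.g. no instruments survive harmonization."""
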