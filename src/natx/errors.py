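"""Exception hierarchy shared by all pipeline stages."""


class NatxError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(NatxError):
    """Malformed input data (bad FASTA/FASTQ/TSV, length mismatches)."""


class AnnotationError(NatxError):
    """A precursor could not be annotated (no ORF, no cleavage site)."""


class PipelineError(NatxError):
    """A pipeline stage failed; the message names the stage."""
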