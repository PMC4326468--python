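"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`EmbryoScreenError`, so callers
(and the CLI) can attach the stage name and sample id uniformly.
"""


class EmbryoScreenError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(EmbryoScreenError):
    """A synthetic genome or simulation spec violates its invariants."""


class InvalidKaryotypeError(EmbryoScreenError):
    """A karyotype event is malformed or outside chromosome bounds."""


class InputMismatchError(EmbryoScreenError):
    """Read input does not match the genome model (unknown contigs etc.)."""


class NoSignalError(EmbryoScreenError):
    """A sample carries no usable signal (e.g. zero autosomal median)."""


class InsufficientDataError(EmbryoScreenError):
    """A statistical comparison was requested on an empty group."""


class AnnotationError(EmbryoScreenError):
    """A call cannot be annotated (e.g. no cytoband covers it)."""


class InconsistentCountsError(EmbryoScreenError):
    """Clinical outcome counts are internally inconsistent."""
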