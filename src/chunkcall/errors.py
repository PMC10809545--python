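"""Exception hierarchy shared across chunkcall modules."""


class ChunkcallError(Exception):
    """Base class for all chunkcall errors."""


class ParseError(ChunkcallError):
    """A text input (fai, CST, VCF annotation, BED) could not be parsed.

    The message names the offending file/line or site so the user can fix
    the input rather than chase a stack trace.
    """


class ValidationError(ChunkcallError):
    """An in-memory object violates a structural invariant."""


class ManifestError(ChunkcallError):
    """A job manifest could not be rendered (bad template, empty inputs)."""


class BoundaryError(ChunkcallError):
    """A variant record lies outside the chunk interval that claims it."""


class DuplicateRecordError(ChunkcallError):
    """The same (chrom, pos, ref, alt) appeared in more than one chunk."""


class UnknownContigError(ChunkcallError):
    """A record or interval references a chromosome missing from the frame."""
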