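"""Exception hierarchy."""


class SplitSVError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SplitSVError):
    """A required input file is missing, unindexed or malformed."""


class RegionError(SplitSVError):
    """A genomic region query is invalid for the given data."""


class SpecError(SplitSVError):
    """A rearrangement specification is inconsistent with the reference."""


class ClassificationError(SplitSVError):
    """Selected reads cannot be reduced to a usable signature."""


class AnnotationError(SplitSVError):
    """Selected reads are inconsistent with the requested annotation."""
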