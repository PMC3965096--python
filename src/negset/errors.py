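"""Exception hierarchy shared across the pipeline stages."""


class NegsetError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(NegsetError):
    """A coordinate file could not be parsed in the requested format."""


class EmptyStructureError(NegsetError):
    """A coordinate file contains no polymer amino-acid chains."""


class MappingIntegrityError(NegsetError):
    """A mapping table assigns conflicting values to the same key."""


class MitabFormatError(NegsetError):
    """A MITAB row is malformed (raised only in strict mode)."""


class DatasetFormatError(NegsetError):
    """A dataset TSV row cannot be parsed."""


class UndefinedFractionError(NegsetError):
    """Removal fraction requested for an empty starting set."""


class NotACandidateError(NegsetError):
    """Confidence score requested for a record that is not a negated
    interaction assertion."""


class FixtureInfeasibleError(NegsetError):
    """The requested pairwise gap geometry cannot be realised."""
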