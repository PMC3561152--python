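"""Exception hierarchy shared across the package."""


class NegevError(Exception):
    """Base class for all package-specific errors."""


class ResolutionError(NegevError):
    """A standoff record references an id that does not resolve."""


class IntegrityError(NegevError):
    """A span's surface string disagrees with the document text."""


class StructureError(NegevError):
    """Event nesting is cyclic or otherwise malformed."""


class LexiconError(NegevError, KeyError):
    """Unknown cue lexicon name."""


class BackendError(NegevError):
    """A parser backend failed on a sentence."""


class MissingFixtureError(BackendError):
    """The fixture backend holds no parse for the requested sentence."""


class AlignmentError(NegevError):
    """A character span could not be aligned to the token stream."""


class SchemaError(NegevError):
    """Feature rows do not share a single feature-name set."""
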